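"""Background-ratio video tracking: blob centroids, speed, freezing.

Each grayscale frame is divided elementwise by a background image taken
without the animal; pixels whose ratio deviates from one mark the mouse
body.  The centroid of the largest connected deviating component is the
animal's position, frame-to-frame displacement times the frame rate gives
speed, and near-zero change of the body mask between adjacent frames marks
freezing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ArenaGeometry, Trajectory

__all__ = [
    "FrameStack",
    "ratio_mask",
    "centroid_track",
    "compute_speed",
    "detect_freezing",
]

log = logging.getLogger(__name__)

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connectivity in 2-D


@dataclass
class FrameStack:
    """An ordered stack of 8-bit grayscale frames plus its background.

    ``frames`` has shape (n, H, W); ``background`` shape (H, W).
    """

    frames: np.ndarray
    background: np.ndarray
    frame_rate: float = 15.0
    mm_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.background = np.asarray(self.background)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if self.frames.shape[1:] != self.background.shape:
            raise ValueError("frames and background shapes differ")
        if self.frame_rate <= 0 or self.mm_per_pixel <= 0:
            raise ValueError("frame_rate and mm_per_pixel must be positive")


def ratio_mask(
    frame: np.ndarray, background: np.ndarray, deviation_tol: float = 0.1
) -> np.ndarray:
    """Pixels where |frame / background - 1| exceeds ``deviation_tol``.

    Zero-background pixels cannot be ratioed; they are excluded from the
    mask with a logged warning.  A tolerance of 0 flags essentially every
    pixel under 8-bit quantization noise and is a misuse of the rule.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    valid = background != 0
    if not valid.all():
        log.warning(
            "%d zero-valued background pixels excluded from ratio mask",
            int((~valid).sum()),
        )
    mask = np.zeros(frame.shape, dtype=bool)
    ratio = np.divide(frame, background, out=np.ones_like(frame), where=valid)
    mask[valid] = np.abs(ratio[valid] - 1.0) > deviation_tol
    return mask


def _largest_component(mask: np.ndarray, min_px: int) -> np.ndarray | None:
    """Boolean mask of the largest 8-connected component with >= min_px pixels."""
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_px:
        return None
    return labels == best


def centroid_track(
    stack: FrameStack,
    deviation_tol: float = 0.1,
    min_blob_px: int = 5,
    subject_id: str = "subject",
    group_label: str = "",
    arena: ArenaGeometry | None = None,
) -> Trajectory:
    """Track the animal as the centroid of the largest body-mask component.

    Positions are reported in mm with pixel (row r, col c) centered at
    ``(c * mm_per_pixel, r * mm_per_pixel)``.  Frames without a qualifying
    component get linearly interpolated positions (copied from the nearest
    valid frame at the ends); body area is the component pixel count times
    mm_per_pixel^2 (NaN where missing).
    """
    if len(stack.frames) < 1:
        raise ValueError("empty frame stack")
    mm = stack.mm_per_pixel
    n = len(stack.frames)
    xy = np.full((n, 2), np.nan)
    areas = np.full(n, np.nan)
    for i, frame in enumerate(stack.frames):
        mask = ratio_mask(frame, stack.background, deviation_tol)
        comp = _largest_component(mask, min_blob_px)
        if comp is None:
            continue
        rows, cols = np.nonzero(comp)
        xy[i] = (cols.mean() * mm, rows.mean() * mm)
        areas[i] = comp.sum() * mm * mm
    valid = ~np.isnan(xy[:, 0])
    if not valid.any():
        raise ValueError("no frame contains a qualifying blob")
    if not valid.all():
        log.warning("%d of %d frames missing a blob; interpolating", int((~valid).sum()), n)
        idx = np.arange(n)
        for k in range(2):
            xy[~valid, k] = np.interp(idx[~valid], idx[valid], xy[valid, k])
    return Trajectory(
        subject_id=subject_id,
        group_label=group_label,
        frame_rate=stack.frame_rate,
        positions=xy,
        arena=arena,
        body_areas=areas,
    )


def compute_speed(trajectory: Trajectory) -> np.ndarray:
    """Instantaneous speed in mm/s: adjacent-step distance x frame rate.

    Returns one value per frame pair (length n_frames - 1).
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least two positions to compute speed")
    steps = np.diff(trajectory.positions, axis=0)
    return np.hypot(steps[:, 0], steps[:, 1]) * trajectory.frame_rate


def detect_freezing(
    body_masks: np.ndarray,
    mm_per_pixel: float,
    threshold: float = 20.0,
    frame_rate: float = 15.0,
    rule: str = "symmetric_difference",
) -> tuple[np.ndarray, float]:
    """Flag freezing frame pairs and total freezing time.

    A pair of adjacent frames is freezing when the body moved by less than
    ``threshold`` mm^2 (strict).  Movement is measured as the area of the
    symmetric difference of the two body masks (``rule =
    'symmetric_difference'``, default: a motionless animal scores ~0) or as
    the absolute change of mask area (``rule = 'area_change'``).

    Returns ``(flags, total_time_s)`` with one flag per frame pair.
    """
    masks = np.asarray(body_masks, dtype=bool)
    if masks.ndim != 3 or len(masks) < 2:
        raise ValueError("need a (n>=2, H, W) stack of body masks")
    px_area = mm_per_pixel * mm_per_pixel
    if rule == "symmetric_difference":
        change = (masks[1:] ^ masks[:-1]).sum(axis=(1, 2)) * px_area
    elif rule == "area_change":
        areas = masks.sum(axis=(1, 2)) * px_area
        change = np.abs(np.diff(areas))
    else:
        raise ValueError(f"unknown freezing rule {rule!r}")
    flags = change < threshold
    return flags, float(flags.sum() / frame_rate)
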