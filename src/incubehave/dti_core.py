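"""Diffusion tensor estimation, scalar maps, and deterministic tractography.

Tensors are estimated voxelwise from the Stejskal-Tanner signal model
S_i = S0 exp(-b_i g_i^T D g_i) by ordinary least squares on log-intensities
(7 parameters: ln S0 and the 6 unique tensor components), using every
measurement including the b=0 rows.  Eigen-decomposition orders
eigenvalues descending; negative fitted eigenvalues are clamped to zero
and flagged.  Scalar maps follow the standard definitions

    MD = (l1 + l2 + l3) / 3        AD = l1
    RD = (l2 + l3) / 2             FA = sqrt(3 S (li - <l>)^2 / (2 S li^2))

Fiber tracking integrates the principal eigenvector field bidirectionally
in fixed physical steps with trilinear interpolation and sign continuity,
terminating on mask exit, low FA, sharp turns, or the length ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DwiAcquisition",
    "TensorVoxelField",
    "ScalarMaps",
    "Streamline",
    "brain_mask",
    "fit_tensor",
    "dti_scalars",
    "fa_from_eigenvalues",
    "track_fibers",
]

log = logging.getLogger(__name__)

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity in 3-D


@dataclass
class DwiAcquisition:
    """A 4-D diffusion-weighted acquisition.

    ``volumes`` has shape (x, y, z, n_meas); ``bvalues`` is 0 for
    T2-weighted rows; ``directions`` are unit vectors (zero rows allowed
    for b=0); ``voxel_size`` is per-axis in micrometers.
    """

    volumes: np.ndarray
    bvalues: np.ndarray
    directions: np.ndarray
    voxel_size: tuple[float, float, float] = (125.0, 125.0, 125.0)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, measurement)")
        n = self.volumes.shape[3]
        if len(self.bvalues) != n or len(self.directions) != n:
            raise ValueError("bvalues/directions must match the measurement axis")
        dwi = self.bvalues > 0
        if dwi.sum() < 6:
            raise ValueError("need at least 6 diffusion-weighted measurements")
        if (self.bvalues == 0).sum() < 1:
            raise ValueError("need at least one b=0 measurement")
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion directions must be unit-norm")
        if np.linalg.matrix_rank(_design_matrix(self.bvalues, self.directions)) < 7:
            raise ValueError("gradient scheme is rank-deficient (collinear directions)")

    @property
    def dwi_mean(self) -> np.ndarray:
        """Per-voxel mean over the diffusion-weighted (b>0) measurements."""
        return self.volumes[..., self.bvalues > 0].mean(axis=-1)


@dataclass
class TensorVoxelField:
    """Per-voxel diffusion tensor eigensystem."""

    tensors: np.ndarray  # (x, y, z, 3, 3), mm^2/s
    eigenvalues: np.ndarray  # (x, y, z, 3) descending, clamped >= 0
    principal_direction: np.ndarray  # (x, y, z, 3) unit e1
    s0: np.ndarray  # (x, y, z)
    in_mask: np.ndarray  # bool
    clamped: np.ndarray  # bool, had a negative raw eigenvalue
    voxel_size: tuple[float, float, float]


@dataclass
class ScalarMaps:
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fa: np.ndarray


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) in micrometers
    seed_voxel: tuple[int, int, int]
    termination: tuple[str, str]  # reason per direction of integration

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    g = bvecs
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def brain_mask(acquisition: DwiAcquisition, min_cluster: int = 10) -> np.ndarray:
    """Half-mean threshold mask with small-cluster removal.

    A voxel is kept when its mean diffusion-weighted intensity is at least
    half the global mean of those per-voxel means; 6-connected clusters
    smaller than ``min_cluster`` voxels are then dropped.
    """
    mean_dwi = acquisition.dwi_mean
    global_mean = float(mean_dwi.mean())
    if global_mean == 0:
        warnings.warn("all-zero diffusion-weighted volume; empty mask", stacklevel=2)
        return np.zeros(mean_dwi.shape, dtype=bool)
    mask = mean_dwi >= 0.5 * global_mean
    labels, n = ndimage.label(mask, structure=_STRUCT_6)
    if n:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes[1:] < min_cluster)[0] + 1
        if len(small):
            mask &= ~np.isin(labels, small)
    return mask


def fit_tensor(
    acquisition: DwiAcquisition, mask: np.ndarray | None = None
) -> TensorVoxelField:
    """Voxelwise log-linear least-squares tensor fit.

    All measurements, including b=0 rows, enter one OLS solve of
    ln S = X beta with the 7-column Stejskal-Tanner design.  Voxels with a
    non-positive intensity in any measurement cannot be log-transformed and
    are flagged out of the fit.
    """
    vols = acquisition.volumes
    shape = vols.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    positive = (vols > 0).all(axis=-1)
    fit_mask = mask & positive
    n_bad = int((mask & ~positive).sum())
    if n_bad:
        log.warning("%d masked voxels with non-positive intensities skipped", n_bad)

    x = _design_matrix(acquisition.bvalues, acquisition.directions)
    flat = vols[fit_mask]  # (n_vox, n_meas)
    beta, *_ = np.linalg.lstsq(x, np.log(flat).T, rcond=None)
    beta = beta.T  # (n_vox, 7)

    tensors = np.zeros(shape + (3, 3))
    eigenvalues = np.zeros(shape + (3,))
    e1 = np.zeros(shape + (3,))
    s0 = np.zeros(shape)
    clamped = np.zeros(shape, dtype=bool)

    d = np.zeros((len(beta), 3, 3))
    d[:, 0, 0] = beta[:, 1]
    d[:, 1, 1] = beta[:, 2]
    d[:, 2, 2] = beta[:, 3]
    d[:, 0, 1] = d[:, 1, 0] = beta[:, 4]
    d[:, 0, 2] = d[:, 2, 0] = beta[:, 5]
    d[:, 1, 2] = d[:, 2, 1] = beta[:, 6]
    evals, evecs = np.linalg.eigh(d)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    neg = evals[:, -1] < 0
    evals_clamped = np.maximum(evals, 0.0)

    tensors[fit_mask] = d
    eigenvalues[fit_mask] = evals_clamped
    e1[fit_mask] = evecs[:, :, 0]
    s0[fit_mask] = np.exp(beta[:, 0])
    clamped[fit_mask] = (evals < 0).any(axis=1) | neg
    return TensorVoxelField(
        tensors=tensors,
        eigenvalues=eigenvalues,
        principal_direction=e1,
        s0=s0,
        in_mask=fit_mask,
        clamped=clamped,
        voxel_size=acquisition.voxel_size,
    )


def fa_from_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalue triples (..., 3), in [0, 1]."""
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = 3.0 * ((lam - mean) ** 2).sum(axis=-1)
    den = 2.0 * (lam**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(np.where(den > 0, num / den, 0.0))
    return np.clip(fa, 0.0, 1.0)


def dti_scalars(field: TensorVoxelField) -> ScalarMaps:
    """MD, AD, RD, and FA maps from the fitted eigensystem."""
    lam = field.eigenvalues
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = (lam[..., 1] + lam[..., 2]) / 2.0
    fa = fa_from_eigenvalues(lam)
    return ScalarMaps(md=md, ad=ad, rd=rd, fa=fa)


# ---------------------------------------------------------------------------
# tractography


def _trilinear_weights(point_vox: np.ndarray, shape: tuple[int, ...]):
    """Corner indices and weights for trilinear interpolation at a voxel-space point."""
    base = np.floor(point_vox).astype(int)
    frac = point_vox - base
    corners, weights = [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + (dx, dy, dz)
                if ((idx < 0) | (idx >= shape)).any():
                    continue
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                if w > 0:
                    corners.append(tuple(idx))
                    weights.append(w)
    return corners, weights


class _FieldSampler:
    """Interpolates FA, e1 (with sign alignment), and mask membership."""

    def __init__(self, field: TensorVoxelField, fa: np.ndarray, interpolation: str):
        self.e1 = field.principal_direction
        self.fa = fa
        self.mask = field.in_mask
        self.voxel_size = np.asarray(field.voxel_size, dtype=float)
        self.shape = field.in_mask.shape
        self.interpolation = interpolation

    def to_voxel(self, point_um: np.ndarray) -> np.ndarray:
        # voxel centers at (index + 0.5) * voxel_size
        return point_um / self.voxel_size - 0.5

    def inside(self, point_um: np.ndarray) -> bool:
        vox = np.rint(self.to_voxel(point_um)).astype(int)
        if ((vox < 0) | (vox >= self.shape)).any():
            return False
        return bool(self.mask[tuple(vox)])

    def sample(self, point_um: np.ndarray, prev_dir: np.ndarray | None):
        """(fa, direction) at a physical point; direction sign-aligned to prev_dir."""
        vox = self.to_voxel(point_um)
        if self.interpolation == "nearest":
            idx = tuple(np.clip(np.rint(vox).astype(int), 0, np.array(self.shape) - 1))
            return float(self.fa[idx]), self.e1[idx].copy()
        corners, weights = _trilinear_weights(vox, self.shape)
        if not corners:
            return 0.0, np.zeros(3)
        fa_val = 0.0
        vec = np.zeros(3)
        ref = prev_dir
        for idx, w in zip(corners, weights):
            fa_val += w * self.fa[idx]
            v = self.e1[idx]
            if ref is None:
                ref = v
            # eigenvectors have arbitrary sign; align before averaging
            vec = vec + w * (v if v @ ref >= 0 else -v)
        return float(fa_val), vec


def _integrate(
    sampler: _FieldSampler,
    start_um: np.ndarray,
    direction: np.ndarray,
    step_um: float,
    max_len_um: float,
    max_angle_deg: float,
    min_fa: float,
) -> tuple[list[np.ndarray], str]:
    """March along the eigenvector field from start in one orientation."""
    cos_limit = np.cos(np.deg2rad(max_angle_deg))
    points: list[np.ndarray] = []
    pos = start_um.copy()
    prev = direction / np.linalg.norm(direction)
    length = 0.0
    while True:
        if length + step_um > max_len_um:
            return points, "max_length"
        fa_val, vec = sampler.sample(pos, prev)
        norm = np.linalg.norm(vec)
        if norm == 0:
            return points, "left_mask"
        step_dir = vec / norm
        if step_dir @ prev < 0:
            step_dir = -step_dir
        if step_dir @ prev < cos_limit:
            return points, "angle"
        nxt = pos + step_um * step_dir
        if not sampler.inside(nxt):
            return points, "left_mask"
        fa_next, _ = sampler.sample(nxt, step_dir)
        if fa_next < min_fa:
            return points, "low_fa"
        points.append(nxt)
        pos = nxt
        prev = step_dir
        length += step_um


def track_fibers(
    field: TensorVoxelField,
    scalars: ScalarMaps,
    seed_region: np.ndarray | list[tuple[int, int, int]],
    step: float = 50.0,
    min_len: float = 750.0,
    max_len: float = 75_000.0,
    max_angle: float = 57.3,
    min_fa: float = 0.4,
    samplings_per_seed: int = 2,
    seed: int = 0,
    interpolation: str = "trilinear",
) -> list[Streamline]:
    """Deterministic FA-guided streamline tracking from a seed region.

    From each seed voxel, ``samplings_per_seed`` start points are jittered
    uniformly within the voxel (seeded, hence reproducible).  Integration
    proceeds bidirectionally along the principal eigenvector with
    ``step``-um steps, terminating on mask exit, FA below ``min_fa``, a
    turning angle above ``max_angle`` degrees, or the per-direction length
    ceiling; streamlines shorter than ``min_len`` um are discarded.
    """
    seeds = [tuple(int(i) for i in v) for v in np.asarray(seed_region).reshape(-1, 3)]
    if not seeds:
        raise ValueError("empty seed region")
    for v in seeds:
        if not field.in_mask[v]:
            raise ValueError(f"seed voxel {v} is outside the mask")
    sampler = _FieldSampler(field, scalars.fa, interpolation)
    voxel_size = np.asarray(field.voxel_size, dtype=float)
    rng = np.random.default_rng(seed)
    streamlines: list[Streamline] = []
    for vox in seeds:
        center = (np.asarray(vox) + 0.5) * voxel_size
        jitters = rng.uniform(-0.5, 0.5, size=(samplings_per_seed, 3)) * voxel_size
        for j in jitters:
            start = center + j
            if not sampler.inside(start):
                continue
            fa0, e0 = sampler.sample(start, None)
            if fa0 < min_fa or np.linalg.norm(e0) == 0:
                continue
            e0 = e0 / np.linalg.norm(e0)
            half = max_len / 2.0
            fwd, reason_f = _integrate(sampler, start, e0, step, half, max_angle, min_fa)
            bwd, reason_b = _integrate(sampler, start, -e0, step, half, max_angle, min_fa)
            pts = np.array(bwd[::-1] + [start] + fwd)
            sl = Streamline(points=pts, seed_voxel=vox, termination=(reason_b, reason_f))
            if sl.length >= min_len:
                streamlines.append(sl)
    return streamlines
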