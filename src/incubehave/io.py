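"""Readers and writers for the pipeline's on-disk formats.

Trajectories travel as tidy CSV, frame stacks as multi-page TIFF plus a
single-page background TIFF, audio as float32 WAV, diffusion data as NIfTI
with FSL-style ``bvals``/``bvecs`` sidecars, and detection/stat outputs as
CSV or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ArenaGeometry, Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_frame_stack",
    "read_frame_stack",
    "write_wav",
    "read_wav",
    "write_dwi_nifti",
    "read_dwi_nifti",
    "write_segments_csv",
    "write_freezing_csv",
    "write_json",
]


def write_trajectory_csv(trajectories: list[Trajectory], path) -> None:
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": t.subject_id,
                    "group": t.group_label,
                    "frame": np.arange(t.n_frames),
                    "t_s": t.times,
                    "x_mm": t.positions[:, 0],
                    "y_mm": t.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(
    path, frame_rate: float = 15.0, arena: ArenaGeometry | None = None
) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=False):
        sub = sub.sort_values("frame")
        out.append(
            Trajectory(
                subject_id=str(sid),
                group_label=str(grp),
                frame_rate=frame_rate,
                positions=sub[["x_mm", "y_mm"]].to_numpy(),
                arena=arena,
            )
        )
    return out


def write_frame_stack(stack: np.ndarray, background: np.ndarray, stack_path, bg_path) -> None:
    import tifffile

    tifffile.imwrite(stack_path, stack)
    tifffile.imwrite(bg_path, background)


def read_frame_stack(stack_path, bg_path) -> tuple[np.ndarray, np.ndarray]:
    import tifffile

    stack = tifffile.imread(stack_path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack, tifffile.imread(bg_path)


def write_wav(waveform: np.ndarray, sample_rate: float, path) -> None:
    from scipy.io import wavfile

    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    return np.asarray(data, dtype=float), float(rate)


def write_dwi_nifti(
    volumes: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    out_dir,
    stem: str = "dwi",
) -> None:
    """NIfTI volume plus FSL-style bvals (one row) and bvecs (three rows)."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*(s / 1000.0 for s in voxel_size_um), 1.0])  # mm units
    nib.save(nib.Nifti1Image(np.asarray(volumes), affine), out_dir / f"{stem}.nii")
    np.savetxt(out_dir / f"{stem}.bval", np.atleast_2d(bvals), fmt="%.1f")
    np.savetxt(out_dir / f"{stem}.bvec", np.asarray(bvecs).T, fmt="%.8f")


def read_dwi_nifti(nii_path, bval_path, bvec_path):
    import nibabel as nib

    img = nib.load(str(nii_path))
    volumes = np.asarray(img.dataobj, dtype=float)
    voxel_size_um = tuple(float(z) * 1000.0 for z in img.header.get_zooms()[:3])
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return volumes, bvals, bvecs, voxel_size_um


def write_segments_csv(segments, path) -> None:
    pd.DataFrame(
        [
            {"start_s": s.start_time, "end_s": s.end_time, "duration_s": s.duration}
            for s in segments
        ],
        columns=["start_s", "end_s", "duration_s"],
    ).to_csv(path, index=False)


def write_freezing_csv(flags: np.ndarray, frame_rate: float, path) -> None:
    """Freezing intervals (start_s, end_s) from per-frame-pair flags."""
    flags = np.asarray(flags, dtype=bool)
    edges = np.diff(np.concatenate([[0], flags.astype(int), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    pd.DataFrame(
        {"start_s": starts / frame_rate, "end_s": ends / frame_rate}
    ).to_csv(path, index=False)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
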