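"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one recording modality of a two-group rodent
stress-incubation study design: arena trajectories with implanted spatial
preference and speed effects, mouse-blob video frames, 250-kHz audio with
inserted ultrasonic chirps, Stejskal-Tanner diffusion-weighted phantoms from
a known tensor field, 4PL-generated ELISA optical-density plates, and
labeled 4-D behavioral state streams.  All generators are deterministic
under a fixed seed.

Trajectories follow a reflected Ornstein-Uhlenbeck process around a
group-specific anchor: stationary, bounded, autocorrelated paths whose
time-average position can be displaced along the stressor axis by a known
amount (the implanted preference effect) and whose step lengths can be
scaled by a known factor (the implanted speed effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ArenaGeometry, Trajectory, light_dark_box

__all__ = [
    "TrajectoryGenSpec",
    "PhantomSpec",
    "ChirpSpec",
    "FourPLParams",
    "DEFAULT_GRADIENT_DIRECTIONS",
    "gen_trajectories",
    "gen_frame_stack",
    "gen_audio",
    "gen_dwi_phantom",
    "gen_state_stream",
    "gen_elisa_plate",
]

# Electrostatic-repulsion set of 30 non-collinear unit gradient directions
# (antipodally symmetrized energy; minimum pairwise separation ~25 deg).
DEFAULT_GRADIENT_DIRECTIONS = np.array(
    [
        (+0.22259466, +0.36089293, -0.90565331),
        (-0.64274058, -0.12909423, -0.75512861),
        (+0.21927671, +0.74607917, -0.62871584),
        (-0.51965928, +0.43307771, +0.73647670),
        (-0.00012175, -0.99595039, -0.08990439),
        (+0.36635884, -0.81075985, -0.45656287),
        (-0.43195915, -0.58670506, -0.68497333),
        (-0.38120471, -0.90025674, +0.21028734),
        (-0.22482227, -0.25647463, -0.94004027),
        (-0.96590094, -0.24810600, -0.07401875),
        (-0.90608538, +0.07476540, -0.41643657),
        (-0.63084245, +0.34210965, -0.69641855),
        (-0.20200853, +0.60575077, -0.76958337),
        (-0.75018804, +0.60490446, +0.26703653),
        (-0.60692584, -0.10806523, +0.78737725),
        (-0.97833031, +0.19382541, +0.07281146),
        (+0.10352982, +0.86010798, +0.49949558),
        (-0.89216468, -0.23499310, +0.38577250),
        (-0.47223239, +0.88147346, -0.00105258),
        (+0.76282318, +0.63820429, -0.10390415),
        (+0.51585589, -0.72989965, +0.44848546),
        (-0.78279825, -0.46174348, -0.41715687),
        (+0.61280900, +0.55059023, -0.56684701),
        (-0.23779815, +0.18688830, -0.95316567),
        (-0.22554687, +0.10998410, +0.96800419),
        (+0.83161428, -0.20854453, -0.51471047),
        (-0.10661187, +0.93015332, -0.35135269),
        (-0.82770664, +0.51888595, -0.21367987),
        (-0.50192861, -0.82986997, -0.24368730),
        (-0.09027586, +0.57521120, +0.81300820),
    ],
    dtype=float,
)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryGenSpec:
    """Configuration for two-group reflected-OU trajectory generation.

    ``preference_shift`` displaces group B's anchor (hence its stationary
    mean position) along the stressor axis, in mm; ``speed_scale``
    multiplies group B's per-step noise, scaling typical step lengths.
    ``noise_sd`` is the per-step diffusion SD in mm at the given frame rate
    and ``ou_relaxation`` the mean-reversion rate toward the anchor in 1/s.
    """

    arena: ArenaGeometry = field(default_factory=light_dark_box)
    n_subjects_per_group: int = 8
    duration: float = 300.0
    frame_rate: float = 15.0
    preference_shift: float = 0.0
    speed_scale: float = 1.0
    ou_relaxation: float = 0.5
    noise_sd: float = 5.0
    anchor: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.speed_scale <= 0:
            raise ValueError("speed_scale must be positive")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] (reflective boundary)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _simulate_group(
    spec: TrajectoryGenSpec,
    anchor: np.ndarray,
    step_sd: float,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler-discretized OU paths for one group, (n_subjects, n_frames, 2)."""
    b = spec.arena.bounds
    dt = 1.0 / spec.frame_rate
    theta = spec.ou_relaxation
    n = spec.n_subjects_per_group
    pos = np.empty((n, n_frames, 2))
    # start at the anchor plus one stationary-scale kick
    stat_sd = step_sd / np.sqrt(max(2.0 * theta * dt, 1e-12))
    pos[:, 0] = anchor + rng.normal(scale=stat_sd, size=(n, 2))
    noise = rng.normal(scale=step_sd, size=(n, n_frames - 1, 2))
    for t in range(1, n_frames):
        drift = theta * dt * (anchor - pos[:, t - 1])
        pos[:, t] = pos[:, t - 1] + drift + noise[:, t - 1]
    pos[..., 0] = _reflect(pos[..., 0], b.xmin, b.xmax)
    pos[..., 1] = _reflect(pos[..., 1], b.ymin, b.ymax)
    return pos


def gen_trajectories(
    spec: TrajectoryGenSpec,
    group_seeds: tuple[int, int] | None = None,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Generate two groups of reflected-OU trajectories.

    Group A is anchored at ``spec.anchor`` (arena center by default); group
    B's anchor is displaced by ``preference_shift`` mm along the stressor
    axis, so the expected time-average axis position differs between groups
    by exactly the implanted shift (up to boundary-reflection truncation).

    Each group gets an independent noise stream derived from ``spec.seed``;
    passing explicit ``group_seeds`` overrides this (the same seed twice
    makes a null-configuration group B bit-identical to group A).

    Returns ``(group_A, group_B)`` lists of :class:`Trajectory`.
    """
    n_frames = int(round(spec.duration * spec.frame_rate))
    b = spec.arena.bounds
    if spec.anchor is None:
        anchor_a = np.array([(b.xmin + b.xmax) / 2.0, (b.ymin + b.ymax) / 2.0])
    else:
        anchor_a = np.asarray(spec.anchor, dtype=float)
    axis = np.asarray(spec.arena.axis_direction, dtype=float)
    anchor_b = anchor_a + spec.preference_shift * axis

    if group_seeds is None:
        rng_a = np.random.default_rng([spec.seed, 0])
        rng_b = np.random.default_rng([spec.seed, 1])
    else:
        rng_a = np.random.default_rng(group_seeds[0])
        rng_b = np.random.default_rng(group_seeds[1])
    pos_a = _simulate_group(spec, anchor_a, spec.noise_sd, n_frames, rng_a)
    pos_b = _simulate_group(
        spec, anchor_b, spec.noise_sd * spec.speed_scale, n_frames, rng_b
    )

    def wrap(positions: np.ndarray, label: str) -> list[Trajectory]:
        return [
            Trajectory(
                subject_id=f"{label}{i:02d}",
                group_label=label,
                frame_rate=spec.frame_rate,
                positions=positions[i],
                arena=spec.arena,
            )
            for i in range(spec.n_subjects_per_group)
        ]

    return wrap(pos_a, "A"), wrap(pos_b, "B")


# ---------------------------------------------------------------------------
# video frames


def gen_frame_stack(
    trajectory: Trajectory,
    blob_radius: float = 10.0,
    image_shape: tuple[int, int] = (128, 128),
    mm_per_pixel: float = 1.0,
    background_level: int = 200,
    blob_contrast: float = 0.5,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Render a trajectory as a stack of 8-bit frames plus a background.

    Each frame is the uniform background with an anti-aliased dark disk
    (intensity ``blob_contrast`` x background) centered at the trajectory
    position; pixel (row r, col c) covers mm coordinates
    ``origin + (c * mm_per_pixel, r * mm_per_pixel)`` at its center, so
    ``origin`` places the imaged field inside an arena coordinate frame.

    Returns ``(stack, background)`` with stack shape (n_frames, H, W), uint8.
    """
    h, w = image_shape
    r_px = blob_radius / mm_per_pixel
    centers = (trajectory.positions - np.asarray(origin)) / mm_per_pixel  # (x=col, y=row)
    if (
        (centers[:, 0] - r_px < -0.5).any()
        or (centers[:, 0] + r_px > w - 0.5).any()
        or (centers[:, 1] - r_px < -0.5).any()
        or (centers[:, 1] + r_px > h - 0.5).any()
    ):
        raise ValueError("blob extends outside the imaged field")
    background = np.full((h, w), background_level, dtype=np.uint8)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    stack = np.empty((len(centers), h, w), dtype=np.uint8)
    for i, (cx, cy) in enumerate(centers):
        dist = np.hypot(rows - cy, cols - cx)
        # coverage ramps over one pixel across the disk edge (anti-aliasing)
        coverage = np.clip(r_px + 0.5 - dist, 0.0, 1.0)
        frame = background_level * (1.0 - (1.0 - blob_contrast) * coverage)
        stack[i] = np.round(frame).astype(np.uint8)
    return stack, background


# ---------------------------------------------------------------------------
# audio


@dataclass
class ChirpSpec:
    """Ultrasonic chirp train riding on white noise.

    ``chirps`` is a list of ``(start_s, duration_s, center_freq_hz,
    amplitude)`` tuples; chirps must not overlap and must respect Nyquist.
    """

    sample_rate: float = 250_000.0
    chirps: list[tuple[float, float, float, float]] = field(default_factory=list)
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        ordered = sorted(self.chirps)
        for start, dur, freq, _amp in ordered:
            if dur <= 0:
                raise ValueError("chirp duration must be positive")
            if freq >= nyq:
                raise ValueError(f"chirp at {freq} Hz exceeds Nyquist {nyq} Hz")
        for (s1, d1, *_), (s2, *_rest) in zip(ordered, ordered[1:]):
            if s1 + d1 > s2:
                raise ValueError("chirps overlap after sorting")


def gen_audio(spec: ChirpSpec, duration: float, seed: int = 0) -> np.ndarray:
    """Synthesize a mono waveform of ``duration`` seconds with the chirps.

    Each chirp is a pure tone at its center frequency with a cosine-tapered
    onset/offset (5% of the chirp length) so its energy stays concentrated
    near ``center_freq``.  Gaussian noise at ``noise_floor`` SD is added
    throughout.  Returns float32 samples in [-1, 1] nominal scale.
    """
    n = int(round(duration * spec.sample_rate))
    rng = np.random.default_rng(seed)
    if spec.noise_floor > 0:
        wave = rng.normal(scale=spec.noise_floor, size=n)
    else:
        wave = np.zeros(n)
    fs = spec.sample_rate
    for start, dur, freq, amp in spec.chirps:
        if start < 0 or start + dur > duration + 1e-12:
            raise ValueError("chirp extends beyond the recording duration")
        i0 = int(round(start * fs))
        i1 = int(round((start + dur) * fs))
        t = np.arange(i1 - i0) / fs
        tone = amp * np.sin(2 * np.pi * freq * t)
        ramp = max(int(0.05 * (i1 - i0)), 1)
        env = np.ones(i1 - i0)
        taper = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = taper
        env[-ramp:] = taper[::-1]
        wave[i0:i1] += tone * env
    return wave.astype(np.float32)


# ---------------------------------------------------------------------------
# DWI phantom


@dataclass
class PhantomSpec:
    """Stejskal-Tanner forward-model phantom.

    ``tensor_field`` maps voxel -> symmetric positive semi-definite 3x3
    diffusion tensor in mm^2/s, given either as an array of shape
    ``grid_shape + (3, 3)`` or a single tensor broadcast to every voxel.
    """

    grid_shape: tuple[int, int, int] = (10, 10, 10)
    voxel_size: float = 125.0  # micrometers, isotropic
    tensor_field: np.ndarray | None = None
    s0: float = 1000.0
    bvalue: float = 2000.0  # s/mm^2
    directions: np.ndarray | None = None
    n_b0: int = 5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.directions is None:
            self.directions = DEFAULT_GRADIENT_DIRECTIONS.copy()
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit-norm")
        if self.tensor_field is None:
            self.tensor_field = np.eye(3) * 7e-4  # isotropic fixed-tissue default
        tf = np.asarray(self.tensor_field, dtype=float)
        if tf.shape == (3, 3):
            tf = np.broadcast_to(tf, self.grid_shape + (3, 3)).copy()
        if tf.shape != self.grid_shape + (3, 3):
            raise ValueError("tensor_field shape must be grid_shape + (3, 3)")
        if not np.allclose(tf, np.swapaxes(tf, -1, -2), atol=1e-12):
            raise ValueError("tensors must be symmetric")
        eigvals = np.linalg.eigvalsh(tf)
        if (eigvals < -1e-12).any():
            raise ValueError("tensors must be positive semi-definite")
        self.tensor_field = tf


def gen_dwi_phantom(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate DWI volumes S_i = S0 * exp(-b g_i^T D g_i) (+ noise).

    Measurements are laid out as ``n_b0`` b=0 rows followed by one row per
    gradient direction.  Additive Gaussian noise of SD ``noise_sd`` is
    applied to the magnitude signal when requested.

    Returns ``(volumes, bvals, bvecs, tensor_field)`` where volumes has
    shape ``grid_shape + (n_meas,)``.
    """
    tf = spec.tensor_field
    dirs = spec.directions
    n_dwi = len(dirs)
    n_meas = spec.n_b0 + n_dwi
    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(n_dwi, spec.bvalue)])
    bvecs = np.concatenate([np.zeros((spec.n_b0, 3)), dirs])
    # g^T D g for every voxel and direction in one einsum
    gdg = np.einsum("id,...de,ie->...i", dirs, tf, dirs)
    volumes = np.empty(spec.grid_shape + (n_meas,))
    volumes[..., : spec.n_b0] = spec.s0
    volumes[..., spec.n_b0 :] = spec.s0 * np.exp(-spec.bvalue * gdg)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volumes = volumes + rng.normal(scale=spec.noise_sd, size=volumes.shape)
    return volumes, bvals, bvecs, tf


# ---------------------------------------------------------------------------
# behavioral state streams


def gen_state_stream(
    class_params: dict[str, tuple[np.ndarray, np.ndarray]],
    n_per_class: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw labeled 4-D behavioral-state samples from Gaussian classes.

    ``class_params`` maps class label -> (mean (4,), covariance (4, 4));
    three classes emulate caffeine-injected, foot-shocked, and non-treated
    recordings.  Returns ``(X, y)`` with X shape (n_classes * n_per_class, 4)
    and y the string labels, grouped by class in dict order.
    """
    if len(class_params) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, (mean, cov) in class_params.items():
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if mean.shape != (4,) or cov.shape != (4, 4):
            raise ValueError("class params must be 4-D mean and 4x4 covariance")
        if (np.linalg.eigvalsh(cov) < -1e-10).any():
            raise ValueError("covariance must be positive semi-definite")
        xs.append(rng.multivariate_normal(mean, cov, size=n_per_class))
        ys.extend([label] * n_per_class)
    return np.concatenate(xs), np.asarray(ys)


# ---------------------------------------------------------------------------
# ELISA plates


@dataclass(frozen=True)
class FourPLParams:
    """Four-parameter logistic curve rho(X) = d + (a-d)/(1+(X/c)^b).

    X is the blank-subtracted optical density; rho the analyte
    concentration in ng/ml.  ``a`` is the minimum-OD asymptote, ``d`` the
    high-OD asymptote, ``c`` the inflection point in OD units, ``b`` the
    Hill slope.  In a competitive-inhibition assay a > d: zero analyte
    yields the highest OD.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("inflection point c must be positive")
        if self.b == 0:
            raise ValueError("Hill slope b must be nonzero")

    def concentration(self, x: np.ndarray) -> np.ndarray:
        """Evaluate rho(X) for blanked OD values X > 0."""
        x = np.asarray(x, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)

    def od_for(self, rho: np.ndarray) -> np.ndarray:
        """Invert the curve: the blanked OD producing concentration rho.

        Concentrations at or beyond the ``d`` asymptote have no finite OD
        and come back as ``inf`` (the caller clips to plate saturation).
        """
        rho = np.asarray(rho, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (self.a - self.d) / (rho - self.d) - 1.0
            x = self.c * np.where(ratio > 0, ratio, np.inf) ** (1.0 / self.b)
        return np.where(np.isclose(rho, self.a), 0.0, x)


DEFAULT_STANDARDS = (0.0, 0.1, 0.4, 1.6, 5.0, 20.0)  # ng/ml CORT series

# Competitive-assay curve whose asymptotes lie beyond the standard series,
# so every default standard (including 0 ng/ml) maps to a finite OD in the
# plate reader's 0-4 range.
DEFAULT_4PL_PARAMS = FourPLParams(a=22.0, b=2.0, c=0.5, d=-0.35)


def gen_elisa_plate(
    params: FourPLParams,
    standard_concentrations: tuple[float, ...] = DEFAULT_STANDARDS,
    blank_od: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    od_saturation: float = 4.0,
):
    """Simulate a duplicate-well standard series plus blank wells.

    Returns a table (pandas DataFrame) with columns ``well_type``
    (standard/blank), ``concentration``, ``replicate`` and ``od``.  Raw ODs
    are the 4PL-inverted values plus the blank offset plus Gaussian noise;
    standards at the curve's asymptote saturate at ``od_saturation`` and are
    flagged in the ``saturated`` column (a competitive assay never reaches
    its zero-analyte asymptote at finite OD).
    """
    import pandas as pd

    if any(c < 0 for c in standard_concentrations):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in standard_concentrations:
        x_true = float(params.od_for(conc))
        saturated = not np.isfinite(x_true)
        if saturated:
            x_true = od_saturation
        for rep in (1, 2):
            od = x_true + blank_od + (rng.normal(scale=noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "well_type": "standard",
                    "concentration": conc,
                    "replicate": rep,
                    "od": od,
                    "saturated": saturated,
                }
            )
    for rep in (1, 2):
        od = blank_od + (rng.normal(scale=noise_sd) if noise_sd else 0.0)
        rows.append(
            {
                "well_type": "blank",
                "concentration": np.nan,
                "replicate": rep,
                "od": od,
                "saturated": False,
            }
        )
    if any(r["saturated"] for r in rows):
        warnings.warn(
            "standards at the 4PL asymptote saturate the plate reader; "
            "flagged in the 'saturated' column",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
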