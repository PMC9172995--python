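"""Fine-scale cumulative behavioral profiling with per-bin significance.

The method summarizes each subject's occupancy along the stressor axis by
T(x), the cumulative time (or probability) of being found at axis positions
<= x, and its speed distribution by U(v), the cumulative probability of
moving at <= v.  Profiles are evaluated on a shared grid; at every grid
point the two groups' per-subject values are compared with a two-tailed
two-sample t-test, and the resulting p-values are displayed as -log10(p)
along the grid and collapsed into a five-number summary.

No correction for multiple comparisons is applied across grid points: the
significance profile is a descriptive scan, not a family of confirmatory
tests, and neighboring bins are strongly dependent by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import Trajectory
from .video_tracking import compute_speed

__all__ = [
    "CumulativeProfile",
    "SignificanceProfile",
    "ZoneMetrics",
    "cumulative_position_profile",
    "cumulative_speed_profile",
    "per_bin_significance",
    "collapse_significance",
    "zone_metrics",
    "default_position_grid",
    "simulate_group_scan",
]

log = logging.getLogger(__name__)


@dataclass
class CumulativeProfile:
    """Per-subject cumulative occupancy curve on a fixed grid.

    ``values[i]`` is the cumulative time in seconds (mode ``time``) or the
    cumulative probability (mode ``probability``) of observations at or
    below ``grid[i]``.
    """

    variable: str  # "position_along_axis" or "speed"
    grid: np.ndarray
    values: np.ndarray
    subject_id: str
    total_time: float
    mode: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or (np.diff(self.grid) <= 0).any():
            raise ValueError("grid must be strictly increasing 1-D")
        if self.values.shape != self.grid.shape:
            raise ValueError("values and grid lengths differ")
        if (np.diff(self.values) < -1e-12).any():
            raise ValueError("cumulative values must be non-decreasing")


@dataclass
class SignificanceProfile:
    """Per-bin -log10(p) of the two-group comparison along the grid."""

    grid: np.ndarray
    neg_log10_p: np.ndarray
    group_sizes: tuple[int, int]
    test: str = "two-sample t (pooled variance), two-tailed"
    degenerate: np.ndarray | None = None  # bins with zero pooled variance

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.neg_log10_p = np.asarray(self.neg_log10_p, dtype=float)
        if self.neg_log10_p.shape != self.grid.shape:
            raise ValueError("neg_log10_p and grid lengths differ")
        if (self.neg_log10_p < 0).any():
            raise ValueError("-log10(p) must be non-negative")


@dataclass
class ZoneMetrics:
    """Classical zone-based summaries of a trajectory."""

    time_in_zone: dict[str, float]
    transfer_count: int
    latency_first_transfer: float
    latency_censored: bool
    time_in_interaction_zone: float | None = None
    entries_from_closed_to_center: int | None = None
    freezing_time: float | None = None
    latency_first_event: float | None = None


def default_position_grid(trajectory: Trajectory, spacing: float = 5.0) -> np.ndarray:
    """Grid at ``spacing`` mm covering the arena's stressor-axis range."""
    lo, hi = trajectory.arena.axis_range()
    return np.arange(lo, hi + spacing, spacing)


def cumulative_position_profile(
    trajectory: Trajectory, grid: np.ndarray, mode: str = "time"
) -> CumulativeProfile:
    """T(x): cumulative time or probability of axis positions <= x."""
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    if mode not in ("time", "probability"):
        raise ValueError("mode must be 'time' or 'probability'")
    grid = np.asarray(grid, dtype=float)
    proj = np.sort(trajectory.axis_positions())
    counts = np.searchsorted(proj, grid, side="right").astype(float)
    total_time = trajectory.n_frames / trajectory.frame_rate
    values = counts / trajectory.frame_rate if mode == "time" else counts / len(proj)
    return CumulativeProfile(
        variable="position_along_axis",
        grid=grid,
        values=values,
        subject_id=trajectory.subject_id,
        total_time=total_time,
        mode=mode,
    )


def cumulative_speed_profile(
    trajectory: Trajectory,
    grid: np.ndarray,
    zone_filter: str | None = None,
    mode: str = "probability",
) -> CumulativeProfile:
    """U(v): cumulative distribution of frame-pair speeds <= v.

    With ``zone_filter``, only frame pairs whose first frame lies inside the
    named zone contribute.
    """
    if trajectory.n_frames < 2:
        raise ValueError("need at least two frames for speeds")
    grid = np.asarray(grid, dtype=float)
    speeds = compute_speed(trajectory)
    if zone_filter is not None:
        inside = trajectory.arena.in_zone(zone_filter, trajectory.positions[:-1])
        speeds = speeds[inside]
        if len(speeds) < 2:
            raise ValueError(f"fewer than two frame pairs inside zone {zone_filter!r}")
    speeds = np.sort(speeds)
    counts = np.searchsorted(speeds, grid, side="right").astype(float)
    total_time = trajectory.n_frames / trajectory.frame_rate
    values = counts / len(speeds) if mode == "probability" else counts / trajectory.frame_rate
    return CumulativeProfile(
        variable="speed",
        grid=grid,
        values=values,
        subject_id=trajectory.subject_id,
        total_time=total_time,
        mode=mode,
    )


def _profile_matrix(profiles: list[CumulativeProfile]) -> np.ndarray:
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid.shape != grid.shape or not np.allclose(p.grid, grid):
            raise ValueError("profiles must share the evaluation grid")
    return np.stack([p.values for p in profiles])


def per_bin_significance(
    profiles_a: list[CumulativeProfile],
    profiles_b: list[CumulativeProfile],
    equal_var: bool = True,
) -> SignificanceProfile:
    """Two-tailed two-sample t-test at every grid point, as -log10(p).

    The pooled-variance (Student) test is the default; Welch via
    ``equal_var=False``.  Bins where both groups are constant are flagged
    degenerate: p is 1 when the group means agree and the machine-minimum
    p-value when they differ (the test statistic diverges).
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("each group needs at least two subjects")
    a = _profile_matrix(profiles_a)
    b = _profile_matrix(profiles_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups evaluated on different grids")
    grid = profiles_a[0].grid
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant bins at the grid tails trip scipy's precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=0)
    var_b = b.var(axis=0)
    degenerate = (var_a == 0) & (var_b == 0)
    if degenerate.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        pvals[degenerate & same_mean] = 1.0
        pvals[degenerate & ~same_mean] = np.finfo(float).tiny
        if (degenerate & ~same_mean).any():
            log.warning(
                "%d zero-variance bins with unequal means set to machine-minimum p",
                int((degenerate & ~same_mean).sum()),
            )
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return SignificanceProfile(
        grid=grid,
        neg_log10_p=-np.log10(pvals),
        group_sizes=(a.shape[0], b.shape[0]),
        test=("two-sample t (pooled variance), two-tailed" if equal_var else "Welch t, two-tailed"),
        degenerate=degenerate,
    )


def collapse_significance(profile: SignificanceProfile) -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max) of -log10(p) values.

    Quartiles use the linear-interpolation convention.
    """
    v = profile.neg_log10_p
    if v.size == 0:
        raise ValueError("empty significance profile")
    qs = np.percentile(v, [0, 25, 50, 75, 100], method="linear")
    return tuple(float(q) for q in qs)


def zone_metrics(
    trajectory: Trajectory,
    zone_names: list[str] | None = None,
    events: np.ndarray | None = None,
    interaction_zone: str | None = None,
    require_partition: bool = False,
) -> ZoneMetrics:
    """Dwell times, transfer counts, and latencies over named arena zones.

    A transfer is a change of zone membership between consecutive frames
    (frames outside every listed zone keep the previous membership so that
    brief unassigned positions do not double-count crossings).  The latency
    to the first transfer is censored at the recording duration when no
    transfer occurs.  ``events`` is an optional array of event timestamps
    in seconds (e.g. rearing) from which the first-event latency is taken.
    """
    arena = trajectory.arena
    if arena is None or not arena.named_zones:
        raise ValueError("trajectory has no arena zones")
    names = zone_names if zone_names is not None else sorted(arena.named_zones)
    membership = np.full(trajectory.n_frames, -1)
    for k, name in enumerate(names):
        inside = arena.in_zone(name, trajectory.positions)
        membership[inside & (membership == -1)] = k
    if require_partition and (membership == -1).any():
        raise ValueError("zones do not partition the visited arena positions")
    dt = 1.0 / trajectory.frame_rate
    time_in = {
        name: float((membership == k).sum() * dt) for k, name in enumerate(names)
    }
    # carry membership forward through unassigned frames
    assigned = membership.copy()
    for i in range(1, len(assigned)):
        if assigned[i] == -1:
            assigned[i] = assigned[i - 1]
    known = assigned != -1
    changes = np.nonzero(known[1:] & known[:-1] & (assigned[1:] != assigned[:-1]))[0]
    transfer_count = int(len(changes))
    duration = trajectory.duration
    if transfer_count:
        latency = float((changes[0] + 1) * dt)
        censored = False
    else:
        latency, censored = duration, True
    interaction_time = None
    if interaction_zone is not None:
        inside = arena.in_zone(interaction_zone, trajectory.positions)
        interaction_time = float(inside.sum() * dt)
    entries_to_center = None
    if "center" in names and any(n.startswith("closed") for n in names):
        closed = [k for k, n in enumerate(names) if n.startswith("closed")]
        center = names.index("center")
        entries_to_center = int(
            np.sum(np.isin(assigned[:-1], closed) & (assigned[1:] == center))
        )
    freezing_time = None
    if trajectory.freezing is not None:
        freezing_time = float(trajectory.freezing.sum() * dt)
    latency_first_event = None
    if events is not None and len(events):
        latency_first_event = float(np.min(events))
    return ZoneMetrics(
        time_in_zone=time_in,
        transfer_count=transfer_count,
        latency_first_transfer=latency,
        latency_censored=censored,
        time_in_interaction_zone=interaction_time,
        entries_from_closed_to_center=entries_to_center,
        freezing_time=freezing_time,
        latency_first_event=latency_first_event,
    )


def simulate_group_scan(
    spec,
    grid: np.ndarray | None = None,
    mode: str = "time",
) -> SignificanceProfile:
    """Generate one two-group study and run the position scan end to end.

    Convenience wrapper used by the calibration studies: draws trajectories
    from a :class:`~incubehave.synthetic_data.TrajectoryGenSpec`, computes
    per-subject T(x) profiles on the grid, and returns the per-bin
    significance profile.
    """
    from .synthetic_data import gen_trajectories

    group_a, group_b = gen_trajectories(spec)
    if grid is None:
        grid = default_position_grid(group_a[0])
    prof_a = [cumulative_position_profile(t, grid, mode) for t in group_a]
    prof_b = [cumulative_position_profile(t, grid, mode) for t in group_b]
    return per_bin_significance(prof_a, prof_b)
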