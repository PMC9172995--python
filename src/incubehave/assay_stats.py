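"""Cross-cutting assay statistics.

One-way ANOVA followed by Tukey's range test (Tukey-Kramer for unequal
group sizes, p-values from the studentized-range distribution), one-tailed
Mann-Whitney U with exact small-sample enumeration, bootstrap standard
errors of percentages and compositions, and the four-parameter logistic
(4PL) ELISA standard curve with blank subtraction and inversion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .synthetic_data import FourPLParams

__all__ = [
    "TukeyResult",
    "anova_tukey",
    "mannwhitney_one_tailed",
    "bootstrap_se",
    "fit_4pl",
    "invert_4pl",
    "blank_subtract",
]

log = logging.getLogger(__name__)


@dataclass
class TukeyResult:
    """ANOVA omnibus results plus Tukey-Kramer pairwise comparisons."""

    f_statistic: float
    anova_p: float
    df_between: int
    df_within: int
    mse: float
    pairs: list[tuple[str, str]]
    mean_differences: np.ndarray
    q_statistics: np.ndarray
    p_adjusted: np.ndarray


def anova_tukey(samples: dict[str, np.ndarray]) -> TukeyResult:
    """One-way ANOVA with Tukey's range test on all group pairs.

    ``samples`` maps group label -> observations.  The pairwise statistic is
    q_ij = |mean_i - mean_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) and the
    adjusted p-value is the studentized-range survival function at q with
    k groups and the within-group degrees of freedom (evaluated by scipy's
    numerical integration of the distribution).  With equal n this reduces
    to q = |mean_i - mean_j| / sqrt(MSE/n).
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(samples[g], dtype=float) for g in labels]
    for g, arr in zip(labels, groups):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} needs at least two observations")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {g!r} contains non-finite observations")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_between, df_within = k - 1, n_total - k
    mse = ss_within / df_within
    if mse == 0:
        if np.allclose(means, means[0]):
            f_stat, anova_p = 0.0, 1.0
        else:
            f_stat, anova_p = np.inf, np.finfo(float).tiny
            log.warning("zero within-group variance with unequal means")
    else:
        f_stat = (ss_between / df_between) / mse
        anova_p = float(stats.f.sf(f_stat, df_between, df_within))

    pairs, diffs, qs, ps = [], [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else np.finfo(float).tiny
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_within))
            pairs.append((labels[i], labels[j]))
            diffs.append(diff)
            qs.append(q)
            ps.append(min(max(p, 0.0), 1.0))
    return TukeyResult(
        f_statistic=float(f_stat),
        anova_p=float(anova_p),
        df_between=df_between,
        df_within=df_within,
        mse=float(mse),
        pairs=pairs,
        mean_differences=np.array(diffs),
        q_statistics=np.array(qs),
        p_adjusted=np.array(ps),
    )


def mannwhitney_one_tailed(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    direction: str,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test.

    ``direction`` is ``"A<B"`` (alternative: A stochastically smaller) or
    ``"A>B"``.  With combined n at or below ``exact_max_n`` and no ties the
    p-value is computed by exact enumeration of rank assignments; otherwise
    the normal approximation with midrank tie correction is used.  Returns
    ``(U_A, p)`` where U_A counts (a > b) pairs plus half the ties.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if direction == "A<B":
        alternative = "less"
    elif direction == "A>B":
        alternative = "greater"
    else:
        raise ValueError("direction must be 'A<B' or 'A>B'")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        if has_ties and len(combined) <= exact_max_n:
            warnings.warn(
                "ties present; falling back to the normal approximation",
                stacklevel=2,
            )
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bootstrap_se(
    observations: np.ndarray,
    statistic=None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> np.ndarray | float:
    """Bootstrap standard error of a statistic over subject-level resamples.

    Each of ``n_boot`` resamples draws len(observations) subjects with
    replacement; the SE is the standard deviation (ddof=1) of the resampled
    statistics.  ``observations`` may be a 1-D array (e.g. binary success
    indicators) or 2-D with one row per subject (e.g. per-subject behavior
    compositions).  The default statistic is the percentage mean
    (``100 * mean``) over axis 0, matching percentage-of-animals and
    percentage-of-time summaries; the SE is then scalar for 1-D input and
    per-category for 2-D input.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValueError("no observations")
    if statistic is None:
        statistic = lambda x: 100.0 * np.mean(x, axis=0)  # noqa: E731
    rng = np.random.default_rng(seed)
    n = len(obs)
    stats_boot = np.array(
        [statistic(obs[rng.integers(0, n, size=n)]) for _ in range(n_boot)]
    )
    se = stats_boot.std(axis=0, ddof=1)
    return float(se) if np.isscalar(se) or se.ndim == 0 else se


def blank_subtract(od: np.ndarray, blank_od: float | np.ndarray) -> np.ndarray:
    """X = <OD> - <OD>_blank: blank-corrected optical densities."""
    return np.asarray(od, dtype=float) - np.mean(blank_od)


def _4pl_curve(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(
    mean_blanked_od: np.ndarray,
    concentrations: np.ndarray,
    max_nfev: int = 10_000,
) -> tuple[FourPLParams, float]:
    """Least-squares 4PL fit of concentration against blanked OD.

    Fits rho(X) = d + (a - d) / (1 + (X/c)^b).  Rows with X <= 0 cannot
    enter the power term and are excluded with a warning.  Initialization:
    ``a``/``d`` from the responses at the smallest/largest X, ``c`` at the X
    nearest the mid-response, ``b = 1``; the optimization is bounded
    (c > 0).  Returns ``(params, residual_sum_of_squares)``.
    """
    x = np.asarray(mean_blanked_od, dtype=float)
    rho = np.asarray(concentrations, dtype=float)
    keep = x > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} standards with non-positive blanked OD excluded",
            stacklevel=2,
        )
        x, rho = x[keep], rho[keep]
    if len(np.unique(x)) < 5:
        raise ValueError("need at least 5 distinct blanked OD values")
    order = np.argsort(x)
    x, rho = x[order], rho[order]
    a0, d0 = rho[0], rho[-1]
    mid = (a0 + d0) / 2.0
    c0 = x[np.argmin(np.abs(rho - mid))]
    if c0 <= 0:
        c0 = np.median(x)
    p0 = [a0, 1.0, c0, d0]
    span = abs(a0 - d0) + 1.0

    def residuals(p):
        return _4pl_curve(x, *p) - rho

    res = optimize.least_squares(
        residuals,
        p0,
        bounds=(
            [a0 - 10 * span, -50.0, 1e-12, d0 - 10 * span],
            [a0 + 10 * span, 50.0, np.inf, d0 + 10 * span],
        ),
        max_nfev=max_nfev,
    )
    if not res.success:
        raise RuntimeError(f"4PL fit did not converge: {res.message}")
    a, b, c, d = res.x
    rss = float(np.sum(res.fun**2))
    return FourPLParams(a=float(a), b=float(b), c=float(c), d=float(d)), rss


def invert_4pl(
    params: FourPLParams,
    sample_od_blanked: float | np.ndarray,
    standard_od_range: tuple[float, float] | None = None,
) -> np.ndarray | float:
    """Concentration of samples from their blanked OD via the fitted curve.

    The 4PL equation maps blanked OD directly to concentration, so this is
    a curve evaluation.  When the standards' blanked-OD range is supplied,
    samples outside [min/2, 2*max] are flagged as extrapolation.
    """
    x = np.asarray(sample_od_blanked, dtype=float)
    if standard_od_range is not None:
        lo, hi = standard_od_range
        out = (x < lo / 2.0) | (x > 2.0 * hi)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} samples outside the calibrated OD range "
                "(extrapolated concentrations)",
                stacklevel=2,
            )
    rho = params.concentration(x)
    return float(rho) if rho.ndim == 0 else rho
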