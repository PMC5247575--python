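"""Decapitated-female proximity assays.

With both females immobile (decapitated, embedded in agar), male
preference is read from dwell time inside a 3 mm radius circle around
each female.  Trials whose total proximity time is under 50 s are
filtered out; per-comparison preference is tested against the 50% null
with Wilcoxon signed-rank tests (exact null for small n); replicates are
checked for homogeneity with a rank-sum test before pooling; and the five
one-tailed per-comparison p-values are combined with Fisher's method,
chi2 = -2 * sum(ln p) on 2k degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "dwell_times",
    "attractiveness_fractions",
    "wilcoxon_vs_half",
    "replicate_homogeneity",
    "fishers_combined",
]

#: proximity radius around each female, mm
RADIUS_MM = 3.0
#: minimum total proximity time for a trial to be analysed, seconds
MIN_TOTAL_S = 50.0


def dwell_times(
    track: np.ndarray | pd.DataFrame,
    pos_plus: tuple[float, float],
    pos_minus: tuple[float, float],
    radius: float = RADIUS_MM,
) -> tuple[float, float]:
    """Time spent inside each female's proximity circle.

    ``track`` is an (n, 3) array or DataFrame of (x, y, t) with strictly
    increasing t (seconds; 0.5 s frames at 2 fps).  Each inter-frame
    interval is credited to a female when the frame's position lies
    within ``radius`` of her (boundary inclusive).  Females must sit more
    than two radii apart, so the circles cannot overlap; were they to,
    both would be credited.
    """
    if isinstance(track, pd.DataFrame):
        track = track[["x", "y", "t"]].to_numpy(dtype=float)
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3 or len(track) < 2:
        raise ValueError("track must be an (n>=2, 3) array of x, y, t")
    t = track[:, 2]
    if not (np.diff(t) > 0).all():
        raise ValueError("track times must be strictly increasing")
    pp = np.asarray(pos_plus, dtype=float)
    pm = np.asarray(pos_minus, dtype=float)
    sep = np.hypot(*(pp - pm))
    if sep <= 2 * radius:
        raise ValueError(
            f"female positions {sep:.2f} mm apart: proximity circles of radius "
            f"{radius} mm would overlap"
        )
    dt = np.diff(t)
    xy = track[:-1, :2]
    d_plus = np.hypot(xy[:, 0] - pp[0], xy[:, 1] - pp[1])
    d_minus = np.hypot(xy[:, 0] - pm[0], xy[:, 1] - pm[1])
    return float(dt[d_plus <= radius].sum()), float(dt[d_minus <= radius].sum())


def attractiveness_fractions(
    trials: pd.DataFrame, min_total: float = MIN_TOTAL_S
) -> tuple[pd.DataFrame, int]:
    """Per-trial fraction of proximity time near the more attractive female.

    Trials with total proximity below ``min_total`` seconds are removed;
    the count removed is returned.  Raises if nothing survives.
    """
    total = trials["t_plus_s"] + trials["t_minus_s"]
    keep = trials[total >= min_total].copy()
    n_filtered = len(trials) - len(keep)
    if keep.empty:
        raise ValueError("all proximity trials fell below the total-time filter")
    keep["fraction_plus"] = keep["t_plus_s"] / (keep["t_plus_s"] + keep["t_minus_s"])
    return keep.reset_index(drop=True), n_filtered


def wilcoxon_vs_half(
    fractions: np.ndarray | pd.Series, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of dwell fractions against 0.5.

    Exact null distribution when n <= 25 with no ties or zeros, normal
    approximation with tie correction otherwise.  ``alternative``
    "greater" tests for preference toward the previously-more-attractive
    female.
    """
    d = np.asarray(fractions, dtype=float) - 0.5
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all fractions equal 0.5: signed-rank test undefined")
    if len(nz) <= 25:
        # exact small-sample null (scipy falls back to a tie-safe method
        # when zeros or tied magnitudes preclude the standard exact table)
        res = stats.wilcoxon(d, alternative=alternative)
    else:
        res = stats.wilcoxon(d, alternative=alternative, method="approx")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ReplicateCheck:
    statistic: float
    p_value: float
    combine: bool


def replicate_homogeneity(
    fractions_by_replicate: dict[str, np.ndarray], alpha: float = 0.05
) -> ReplicateCheck:
    """Rank-sum comparison of dwell fractions between two replicates.

    Replicates are pooled downstream only when no difference is detected
    (p >= alpha); otherwise callers should analyse them separately.
    """
    if len(fractions_by_replicate) != 2:
        raise ValueError("expected exactly 2 replicate groups")
    (ra, a), (rb, b) = sorted(fractions_by_replicate.items())
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each replicate needs at least 2 trials")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    combine = bool(res.pvalue >= alpha)
    if not combine:
        import warnings

        warnings.warn(
            f"replicates {ra}/{rb} differ (rank-sum p={res.pvalue:.4g}); analyse separately"
        )
    return ReplicateCheck(float(res.statistic), float(res.pvalue), combine)


def fishers_combined(one_tailed_ps) -> tuple[float, int, float]:
    """Fisher's combined probability over independent one-tailed tests.

    chi2 = -2 * sum(ln p_i) on 2k degrees of freedom; returns
    (chi2, df, p).  A p of exactly 1 contributes 0.
    """
    ps = np.asarray(list(one_tailed_ps), dtype=float)
    if len(ps) == 0:
        raise ValueError("no p-values to combine")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(ps).sum())
    df = 2 * len(ps)
    return chi2, df, float(stats.chi2.sf(chi2, df))
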