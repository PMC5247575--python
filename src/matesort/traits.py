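"""Female-trait summaries and trait-preference permutation inference.

The central device is a pairwise-difference correlation: for every
canonical line pair (i, j) the preference proportion for line i is
correlated with the trait difference trait_i - trait_j.  Because the 45
pair differences derive from only 10 line measurements, significance is
assessed by permuting the line-to-trait assignment (the line is the unit
of replication), recomputing every difference and the correlation, with
the add-one p-value convention.

Also here: the receptivity score (slowest line scores 0; higher = more
receptive), individual-level receptivity randomizations with 200-minute
censoring substitution, the |r| > 0.5 hydrocarbon screen, one-way ANOVA
on mass, a Gaussian LRT for line effects on log receptivity times, and
geometric-mean (standardized major axis) regression used for display
fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .network import ChoiceNetwork, Ranking
from .permutation import PermutationResult, pearson_r, pearson_r_many, perm_rng

__all__ = [
    "PairwiseAssociation",
    "receptivity_score",
    "preference_trait_correlation",
    "preference_pairdiff_correlation",
    "individual_receptivity_differences",
    "pairwise_individual_differences",
    "screen_chcs",
    "anova_mass",
    "lrt_receptivity",
    "sma_slope",
]


@dataclass
class PairwiseAssociation:
    """Per-pair preference vs trait-difference table with permutation inference."""

    trait_name: str
    pairs: pd.DataFrame  # line_i, line_j, preference, trait_diff
    r: float
    perm: PermutationResult
    n_dropped_pairs: int = 0


def receptivity_score(line_means: pd.Series) -> pd.Series:
    """Receptivity score per line: max line-mean time minus the line's mean.

    The slowest (least receptive) line scores 0; higher scores mean more
    receptive.  Input means should come from uncensored observations
    only.
    """
    means = line_means.dropna()
    dropped = set(line_means.index) - set(means.index)
    if dropped:
        import warnings

        warnings.warn(f"lines without uncensored observations excluded: {sorted(dropped)}")
    return means.max() - means


def _pair_table(net: ChoiceNetwork, trait: pd.Series) -> pd.DataFrame:
    rows = []
    for a, b in combinations(sorted(net.lines), 2):
        p = net.pref.loc[a, b]
        rows.append(
            {
                "line_i": a,
                "line_j": b,
                "preference": p,
                "trait_diff": trait[a] - trait[b],
            }
        )
    return pd.DataFrame(rows)


def preference_trait_correlation(
    net: ChoiceNetwork,
    trait: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
    trait_name: str = "trait",
) -> PairwiseAssociation:
    """Correlate pair preferences with pairwise trait differences.

    ``trait`` holds one value per line.  The permutation shuffles the
    line-to-trait assignment and recomputes all pairwise differences, so
    the p-value respects line-level dependence among the pairs.
    """
    missing = [l for l in net.lines if l not in trait.index]
    if missing:
        raise ValueError(f"trait missing for lines {missing}")
    if np.ptp(trait[list(net.lines)].to_numpy(dtype=float)) == 0:
        raise ValueError(f"trait {trait_name!r} constant across lines: correlation undefined")

    full = _pair_table(net, trait)
    table = full.dropna(subset=["preference"])
    n_dropped = len(full) - len(table)
    if len(table) < 3:
        raise ValueError("fewer than 3 pairs with defined preference")

    lines = sorted(net.lines)
    tvals = trait[lines].to_numpy(dtype=float)
    li = [lines.index(x) for x in table["line_i"]]
    lj = [lines.index(x) for x in table["line_j"]]
    y = table["preference"].to_numpy(dtype=float)
    x_obs = tvals[li] - tvals[lj]
    if np.ptp(x_obs) == 0:
        raise ValueError("all pairwise trait differences are zero")
    r_obs = pearson_r(x_obs, y)

    rng = perm_rng(seed)
    perms = np.array([rng.permutation(len(lines)) for _ in range(n_perm)])
    X = tvals[perms[:, li]] - tvals[perms[:, lj]]
    r_perm = pearson_r_many(X, y)
    n_exceed = _exceed(r_perm, r_obs, sidedness)
    res = PermutationResult.from_counts(
        observed=r_obs, n_perm=n_perm, n_exceed=n_exceed, seed=seed, sidedness=sidedness
    )
    return PairwiseAssociation(trait_name, table.reset_index(drop=True), r_obs, res, n_dropped)


def _exceed(r_perm: np.ndarray, r_obs: float, sidedness: str) -> int:
    r_perm = np.nan_to_num(r_perm, nan=0.0)
    eps = 1e-12
    if sidedness == "two-sided":
        return int((np.abs(r_perm) >= abs(r_obs) - eps).sum())
    if sidedness == "greater":
        return int((r_perm >= r_obs - eps).sum())
    if sidedness == "less":
        return int((r_perm <= r_obs + eps).sum())
    raise ValueError(f"unknown sidedness {sidedness!r}")


def preference_pairdiff_correlation(
    net: ChoiceNetwork,
    diffs: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
    trait_name: str = "pair_diff",
) -> PairwiseAssociation:
    """Like :func:`preference_trait_correlation` but for precomputed
    antisymmetric per-pair differences (e.g. individual-level receptivity
    randomizations).

    ``diffs`` is indexed by canonical (line_i, line_j) pairs and holds the
    i-minus-j difference.  The line-label permutation maps pair (i, j) to
    (sigma(i), sigma(j)), negating the stored value when the image pair is
    stored in the opposite order.
    """
    lines = sorted(net.lines)
    n = len(lines)
    dmat = np.zeros((n, n))
    for (a, b), d in diffs.items():
        ia, ib = lines.index(a), lines.index(b)
        dmat[ia, ib] = d
        dmat[ib, ia] = -d

    ps = net.pair_series()
    rows = []
    for (a, b), p in ps.items():
        if (a, b) in diffs.index:
            rows.append(
                {"line_i": a, "line_j": b, "preference": p, "trait_diff": diffs[(a, b)]}
            )
    table = pd.DataFrame(rows).dropna(subset=["preference"])
    if len(table) < 3:
        raise ValueError("fewer than 3 pairs with defined preference and difference")
    li = [lines.index(x) for x in table["line_i"]]
    lj = [lines.index(x) for x in table["line_j"]]
    y = table["preference"].to_numpy(dtype=float)
    x_obs = dmat[li, lj]
    r_obs = pearson_r(x_obs, y)

    rng = perm_rng(seed)
    li = np.asarray(li)
    lj = np.asarray(lj)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    X = dmat[perms[:, li], perms[:, lj]]
    r_perm = pearson_r_many(X, y)
    n_exceed = _exceed(r_perm, r_obs, sidedness)
    res = PermutationResult.from_counts(
        observed=r_obs, n_perm=n_perm, n_exceed=n_exceed, seed=seed, sidedness=sidedness
    )
    return PairwiseAssociation(trait_name, table.reset_index(drop=True), r_obs, res, 0)


def individual_receptivity_differences(
    obs_a: pd.DataFrame,
    obs_b: pd.DataFrame,
    seed: int = 0,
    censor_minutes: float = 200.0,
) -> float:
    """Mean within-pair courtship-to-mating difference between two lines.

    Individuals of line A are randomly paired without replacement with
    individuals of line B (excess individuals unpaired); censored
    individuals enter at the censoring maximum.  Returns the mean A-minus-B
    difference in minutes.
    """
    if len(obs_a) == 0 or len(obs_b) == 0:
        raise ValueError("empty observation set")

    def times(df: pd.DataFrame) -> np.ndarray:
        t = df["minutes"].to_numpy(dtype=float).copy()
        t[df["censored"].to_numpy(dtype=bool)] = censor_minutes
        return t

    ta, tb = times(obs_a), times(obs_b)
    rng = np.random.default_rng(seed)
    k = min(len(ta), len(tb))
    ta = rng.permutation(ta)[:k]
    tb = rng.permutation(tb)[:k]
    return float(np.mean(ta - tb))


def pairwise_individual_differences(
    obs: pd.DataFrame,
    lines: list[str],
    seed: int = 0,
    censor_minutes: float = 200.0,
) -> pd.Series:
    """Per-pair mean individual receptivity differences for all canonical pairs."""
    rng = np.random.default_rng(seed)
    idx, vals = [], []
    for a, b in combinations(sorted(lines), 2):
        d = individual_receptivity_differences(
            obs[obs["line"] == a],
            obs[obs["line"] == b],
            seed=int(rng.integers(0, 2**31 - 1)),
            censor_minutes=censor_minutes,
        )
        idx.append((a, b))
        vals.append(d)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["line_i", "line_j"]))


def screen_chcs(
    chc_means: pd.DataFrame,
    ranking: Ranking,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Screen hydrocarbon peaks for substantial correlation with attractiveness.

    ``chc_means`` is lines x peaks (line-mean relative abundances).  Each
    peak is correlated with the Copeland attractiveness score; peaks with
    |r| above the threshold are returned sorted by |r| descending.
    Constant peaks are excluded and listed in the ``note`` column of the
    (full) returned screen.
    """
    if len(chc_means) < 3:
        raise ValueError("need at least 3 lines to screen CHCs")
    scores = ranking.scores()
    lines = [l for l in chc_means.index if l in scores.index]
    s = scores[lines].to_numpy(dtype=float)
    rows = []
    for peak in chc_means.columns:
        v = chc_means.loc[lines, peak].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(s) == 0:
            rows.append({"peak": peak, "r": np.nan, "selected": False, "note": "constant"})
            continue
        r = pearson_r(v, s)
        rows.append(
            {"peak": peak, "r": r, "selected": bool(abs(r) > threshold), "note": ""}
        )
    out = pd.DataFrame(rows)
    out["abs_r"] = out["r"].abs()
    return out.sort_values("abs_r", ascending=False, na_position="last").drop(
        columns="abs_r"
    ).reset_index(drop=True)


def anova_mass(groups: dict[str, np.ndarray] | pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of individual mass by line, from sums of squares.

    Accepts either a mapping line -> values or a long DataFrame with
    ``line`` and ``mass_mg`` columns.  Returns (F, (df_between,
    df_within), p).  Complete separation (zero within-group variance with
    nonzero between) reports F = inf, p = 0.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {l: g["mass_mg"].to_numpy(dtype=float) for l, g in groups.groupby("line")}
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    if k < 2:
        raise ValueError("need at least 2 lines")
    if n - k <= 0:
        raise ValueError("zero residual degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, (df_b, df_w), 1.0
        return float("inf"), (df_b, df_w), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), (df_b, df_w), float(stats.f.sf(f, df_b, df_w))


def lrt_receptivity(
    obs: pd.DataFrame, log_scale: bool = True
) -> tuple[float, int, float]:
    """Likelihood-ratio test for a line effect on courtship-to-mating times.

    Gaussian fixed-effects model of (log) time on female line and male
    line; the reduced model drops the female-line factor.  Uncensored
    observations only.  Returns (chi2, df, p).
    """
    d = obs[~obs["censored"].astype(bool)].copy()
    if d.empty:
        raise ValueError("no uncensored observations")
    y = np.log(d["minutes"].to_numpy(dtype=float)) if log_scale else d[
        "minutes"
    ].to_numpy(dtype=float)
    import statsmodels.api as sm

    def design(with_line: bool) -> np.ndarray:
        parts = [np.ones((len(d), 1))]
        if with_line:
            parts.append(pd.get_dummies(d["line"], drop_first=True).to_numpy(dtype=float))
        if d["male_line"].nunique() > 1:
            parts.append(
                pd.get_dummies(d["male_line"], drop_first=True).to_numpy(dtype=float)
            )
        return np.hstack(parts)

    full = sm.OLS(y, design(True)).fit()
    reduced = sm.OLS(y, design(False)).fit()
    stat = 2.0 * (full.llf - reduced.llf)
    df = int(full.df_model - reduced.df_model)
    return float(stat), df, float(stats.chi2.sf(stat, df))


def sma_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Geometric-mean (standardized major axis) regression slope and intercept.

    slope = sign(r) * sd(y)/sd(x); the line passes through the means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = pearson_r(x, y)
    slope = np.sign(r) * sy / sx if r != 0 else sy / sx
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)
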