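"""Choice networks from two-female trial records.

A trial pits two female lines against one male; the mated line (if any)
scores a "win" for her line.  Aggregating wins over all unordered pairs
gives a win matrix; pairwise preference proportions orient a choice
network (an arrow points from the preferred line to its rival, exactly
0.5 or no matings is a tie); Copeland scores (lines beaten) rank lines by
attractiveness.

Pair proportions are aligned across different chooser genotypes by a
canonical lexicographic pair order, so mating biases can be correlated
between choosers with significance from line-label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd

from .permutation import PermutationResult, pearson_r, perm_rng

__all__ = [
    "WinMatrix",
    "ChoiceNetwork",
    "Ranking",
    "build_win_matrix",
    "preferences_and_orientation",
    "copeland_ranking",
    "mating_rate",
    "cross_chooser_correlation",
]


@dataclass
class WinMatrix:
    """Square win-count table; ``wins[i, j]`` = matings won by line i in (i, j) trials."""

    lines: list[str]
    wins: pd.DataFrame
    #: total trials per unordered pair, including no-mating trials
    n_trials: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.wins.to_numpy()
        if (w < 0).any() or np.diag(w).any():
            raise ValueError("win matrix must be nonnegative with zero diagonal")


@dataclass
class ChoiceNetwork:
    """Oriented choice network over female lines.

    ``pref.loc[i, j]`` is the proportion of (i, j) matings won by i (NaN
    where no matings were observed).  ``no_data`` lists pairs with no
    matings at all; these are ties flagged as data-free.
    """

    lines: list[str]
    pref: pd.DataFrame
    wins: pd.DataFrame | None = None
    no_data: set = field(default_factory=set)

    def orientation(self, a: str, b: str) -> str | None:
        """Winner of the (a, b) edge, or None for a tie/undefined pair."""
        p = self.pref.loc[a, b]
        if pd.isna(p) or p == 0.5:
            return None
        return a if p > 0.5 else b

    def is_tie(self, a: str, b: str) -> bool:
        return self.orientation(a, b) is None

    def graph(self) -> nx.DiGraph:
        """Resolved edges as a directed graph (ties omitted)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.lines)
        for a, b in combinations(self.lines, 2):
            w = self.orientation(a, b)
            if w is not None:
                loser = b if w == a else a
                g.add_edge(w, loser)
        return g

    def pair_series(self) -> pd.Series:
        """Preference proportion for the first line of each canonical pair.

        Index is (i, j) with i < j lexicographically; NaN where undefined.
        """
        idx, vals = [], []
        for a, b in combinations(sorted(self.lines), 2):
            idx.append((a, b))
            vals.append(self.pref.loc[a, b])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["line_i", "line_j"]))

    def subset(self, keep: list[str]) -> "ChoiceNetwork":
        keep = [l for l in self.lines if l in set(keep)]
        wins = self.wins.loc[keep, keep] if self.wins is not None else None
        nd = {p for p in self.no_data if p[0] in set(keep) and p[1] in set(keep)}
        return ChoiceNetwork(keep, self.pref.loc[keep, keep], wins, nd)

    @classmethod
    def from_preferences(cls, pref: dict[tuple[str, str], float]) -> "ChoiceNetwork":
        """Build from a dict of canonical-pair preferences (p for the first line)."""
        lines = sorted({l for pair in pref for l in pair})
        mat = pd.DataFrame(np.nan, index=lines, columns=lines)
        for (a, b), p in pref.items():
            if p is not None and not pd.isna(p):
                mat.loc[a, b] = p
                mat.loc[b, a] = 1.0 - p
        return cls(lines, mat)


@dataclass
class Ranking:
    """Copeland scores (lines beaten) with competition ranking."""

    table: pd.DataFrame  # columns: line, score, rank

    def scores(self) -> pd.Series:
        return self.table.set_index("line")["score"]


def build_win_matrix(
    trials: pd.DataFrame, condition: str | None = None, lines: list[str] | None = None
) -> WinMatrix:
    """Aggregate trial records into a win matrix.

    Trials with no mating contribute to neither win cell but are counted
    in ``n_trials`` so mating rates remain computable.  ``lines`` fixes
    the matrix axes explicitly (useful when the trial table is empty or a
    line never mated).
    """
    t = trials if condition is None else trials[trials["condition"] == condition]
    if lines is None:
        lines = sorted(set(t["line_a"]) | set(t["line_b"]))
    else:
        lines = sorted(lines)
    wins = pd.DataFrame(0, index=lines, columns=lines, dtype=int)
    n_tr = pd.DataFrame(0, index=lines, columns=lines, dtype=int)
    for _, row in t.iterrows():
        a, b, m = row["line_a"], row["line_b"], row["mated_line"]
        n_tr.loc[a, b] += 1
        n_tr.loc[b, a] += 1
        if m is None or (isinstance(m, float) and np.isnan(m)) or m == "":
            continue
        if m not in (a, b):
            raise ValueError(f"mated_line {m!r} not among trial lines {a!r}, {b!r}")
        loser = b if m == a else a
        wins.loc[m, loser] += 1
    return WinMatrix(lines, wins, n_tr)


def preferences_and_orientation(wm: WinMatrix) -> ChoiceNetwork:
    """Preference proportions and edge orientations from a win matrix.

    ``p[i, j] = W[i, j] / (W[i, j] + W[j, i])`` where matings were
    observed; pairs with no matings are ties flagged as data-free.
    """
    lines = wm.lines
    w = wm.wins.to_numpy(dtype=float)
    tot = w + w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, w / tot, np.nan)
    np.fill_diagonal(p, np.nan)
    pref = pd.DataFrame(p, index=lines, columns=lines)
    no_data = {
        (a, b)
        for a, b in combinations(sorted(lines), 2)
        if tot[lines.index(a), lines.index(b)] == 0
    }
    return ChoiceNetwork(list(lines), pref, wins=wm.wins.copy(), no_data=no_data)


def copeland_ranking(net: ChoiceNetwork) -> Ranking:
    """Rank lines by the number of rivals beaten over resolved edges.

    Ties in score share a rank (competition ranking: rank = 1 + number of
    strictly higher scores); output ordered by (rank, line label).
    """
    g = net.graph()
    scores = {l: g.out_degree(l) for l in net.lines}
    vals = pd.Series(scores)
    rank = {l: int(1 + (vals > s).sum()) for l, s in scores.items()}
    tab = pd.DataFrame(
        {"line": list(scores), "score": list(scores.values()), "rank": [rank[l] for l in scores]}
    ).sort_values(["rank", "line"], kind="stable").reset_index(drop=True)
    n_resolved = sum(
        1 for a, b in combinations(net.lines, 2) if net.orientation(a, b) is not None
    )
    assert tab["score"].sum() == n_resolved
    return Ranking(tab)


def mating_rate(trials: pd.DataFrame) -> pd.DataFrame:
    """Mating rate with binomial standard error, per chooser condition."""
    rows = []
    for cond, grp in trials.groupby("condition"):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty trial group for condition {cond!r}")
        mated = grp["mated_line"].map(
            lambda m: not (m is None or (isinstance(m, float) and np.isnan(m)) or m == "")
        )
        rate = mated.sum() / n
        rows.append(
            {
                "condition": cond,
                "n_trials": n,
                "rate": rate,
                "sem": float(np.sqrt(rate * (1.0 - rate) / n)),
            }
        )
    return pd.DataFrame(rows)


def _aligned_pair_arrays(
    net_a: ChoiceNetwork, net_b: ChoiceNetwork
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    if set(net_a.lines) != set(net_b.lines):
        raise ValueError("networks must share the same line set")
    lines = sorted(net_a.lines)
    pa = net_a.pref.loc[lines, lines].to_numpy()
    pb = net_b.pref.loc[lines, lines].to_numpy()
    iu, ju = np.triu_indices(len(lines), k=1)
    xa, xb = pa[iu, ju], pb[iu, ju]
    ok = ~(np.isnan(xa) | np.isnan(xb))
    n_dropped = int((~ok).sum())
    return xa[ok], iu[ok], ju[ok], lines, n_dropped


def cross_chooser_correlation(
    net_a: ChoiceNetwork,
    net_b: ChoiceNetwork,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[PermutationResult, int]:
    """Pearson correlation of pair preferences between two choosers.

    The 45 canonical-pair proportions (first line of each lexicographic
    pair) are correlated between the two networks; pairs undefined in
    either network are dropped pairwise-complete (the count of dropped
    pairs is returned).  Significance comes from permuting the line
    labels of the second network — the line, not the pair, is the unit of
    replication — with the two-sided add-one p-value convention.
    """
    xa, iu, ju, lines, n_dropped = _aligned_pair_arrays(net_a, net_b)
    if len(xa) < 3:
        raise ValueError("fewer than 3 shared defined pairs")
    pb = net_b.pref.loc[lines, lines].to_numpy()
    xb = pb[iu, ju]
    r_obs = pearson_r(xa, xb)

    n = len(lines)
    rng = perm_rng(seed)
    n_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xb_p = pb[perm[iu], perm[ju]]
        ok = ~np.isnan(xb_p)
        if ok.sum() < 3 or np.nanstd(xb_p[ok]) == 0 or np.std(xa[ok]) == 0:
            continue
        r_p = pearson_r(xa[ok], xb_p[ok])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            n_exceed += 1
    res = PermutationResult.from_counts(
        observed=r_obs, n_perm=n_perm, n_exceed=n_exceed, seed=seed, sidedness="two-sided"
    )
    return res, n_dropped
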