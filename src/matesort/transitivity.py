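"""Triad transitivity of a choice network.

Any three lines with all three pairwise edges resolved form either a
transitive triad (one line beats both others, one loses to both) or a
cyclic one (rock-paper-scissors).  Of the 8 orientations of a labeled
triangle, 6 are transitive and 2 cyclic, so a random tournament is
expected to be 75% transitive.  The network statistic

    t_tri = n_transitive / (n_transitive + n_cyclic)

excludes tie-containing triads from both numerator and denominator (the
standard dominance-hierarchy convention); its significance comes from
re-orienting every resolved edge at random (ties held fixed) and counting
replicates whose t_tri is at least the observed value.

Strength of transitivity is classified per ordered transitive triad
a > b > c from its preference probabilities: weak requires all three
P >= 0.5 (guaranteed by edge-consistent ordering), moderate requires
P(a,c) >= min(P(a,b), P(b,c)), strong requires P(a,c) >= max(...).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

from .network import ChoiceNetwork, Ranking
from .permutation import PermutationResult, perm_rng

__all__ = [
    "TriadCensus",
    "StochasticTransitivityReport",
    "UndefinedTransitivityError",
    "triad_census",
    "t_tri",
    "permutation_test_transitivity",
    "stochastic_transitivity",
    "simulate_random_tournaments",
]


class UndefinedTransitivityError(ValueError):
    """t_tri is undefined: no fully resolved triads in the network."""


@dataclass(frozen=True)
class TriadCensus:
    n_transitive: int
    n_cyclic: int
    n_with_tie: int

    @property
    def n_resolved(self) -> int:
        return self.n_transitive + self.n_cyclic

    @property
    def n_total(self) -> int:
        return self.n_transitive + self.n_cyclic + self.n_with_tie


@dataclass(frozen=True)
class StochasticTransitivityReport:
    n_eligible_triads: int
    weak_violations: int
    moderate_violations: int
    strong_violations: int
    n_cyclic: int
    n_with_tie: int

    def __post_init__(self) -> None:
        if not (
            self.strong_violations >= self.moderate_violations >= self.weak_violations
        ):
            raise ValueError("violation counts must be nested strong >= moderate >= weak")

    def fraction(self, kind: str) -> float:
        n = getattr(self, f"{kind}_violations")
        return n / self.n_eligible_triads if self.n_eligible_triads else float("nan")


def triad_census(net: ChoiceNetwork) -> TriadCensus:
    """Classify every unordered line triple.

    Delegates to the directed triadic census: type 030T is transitive,
    030C cyclic; every remaining triple contains at least one tie (or
    data-free) edge.
    """
    if len(net.lines) < 3:
        raise ValueError("triad census needs at least 3 lines")
    census = nx.triadic_census(net.graph())
    n_tr, n_cy = census["030T"], census["030C"]
    total = comb(len(net.lines), 3)
    return TriadCensus(n_tr, n_cy, total - n_tr - n_cy)


def t_tri(census: TriadCensus) -> float:
    """Proportion of resolved triads that are transitive."""
    if census.n_resolved == 0:
        raise UndefinedTransitivityError(
            "no resolved triads: t_tri is undefined for this network"
        )
    return census.n_transitive / census.n_resolved


def _resolved_edges_and_triads(
    net: ChoiceNetwork,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Resolved edges (canonical order) and index triples of resolved triads.

    For a triad with lines a < b < c and edge bits x_ab, x_bc, x_ac (1 if
    the lexicographically lower line wins), the triad is cyclic iff
    x_ab == x_bc and x_ac == 1 - x_ab.
    """
    lines = sorted(net.lines)
    edges = []
    bits = {}
    for a, b in combinations(lines, 2):
        w = net.orientation(a, b)
        if w is not None:
            bits[(a, b)] = 1 if w == a else 0
            edges.append((a, b))
    eidx = {e: k for k, e in enumerate(edges)}
    triads = []
    for a, b, c in combinations(lines, 3):
        if (a, b) in eidx and (b, c) in eidx and (a, c) in eidx:
            triads.append((eidx[(a, b)], eidx[(b, c)], eidx[(a, c)]))
    obs_bits = np.array([bits[e] for e in edges], dtype=np.uint8)
    return edges, obs_bits, np.array(triads, dtype=np.intp).reshape(-1, 3)


def _count_cyclic(bits: np.ndarray, triads: np.ndarray) -> np.ndarray:
    """Cyclic-triad count per replicate; ``bits`` is (n_reps, n_edges)."""
    x_ab = bits[:, triads[:, 0]]
    x_bc = bits[:, triads[:, 1]]
    x_ac = bits[:, triads[:, 2]]
    cyc = (x_ab == x_bc) & (x_ac == 1 - x_ab)
    return cyc.sum(axis=1)


def permutation_test_transitivity(
    net: ChoiceNetwork,
    n_perm: int = 100_000,
    seed: int = 0,
    randomized: bool = False,
) -> PermutationResult:
    """Direction-randomization test of network transitivity.

    Each replicate independently re-orients every resolved edge with
    probability 1/2 each way (ties stay ties), and the exceedance count
    is the number of replicates whose t_tri is >= the observed value.
    Because ties are fixed, the resolved-triad denominator is constant,
    so the comparison reduces to an exact integer comparison of
    transitive-triad counts — no floating-point tie-breaking.

    With ``randomized=True`` a tie-broken p-value (exactly uniform under
    the null) is attached for calibration diagnostics.
    """
    _, obs_bits, triads = _resolved_edges_and_triads(net)
    if len(triads) == 0:
        raise UndefinedTransitivityError("t_tri undefined: no resolved triads")
    n_resolved_triads = len(triads)
    obs_cyc = int(_count_cyclic(obs_bits[None, :], triads)[0])
    obs_trans = n_resolved_triads - obs_cyc

    rng = perm_rng(seed)
    n_edges = len(obs_bits)
    n_exceed = 0
    n_tied = 0
    chunk = max(1, min(n_perm, 20_000))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        bits = rng.integers(0, 2, size=(m, n_edges), dtype=np.uint8)
        cyc = _count_cyclic(bits, triads)
        trans = n_resolved_triads - cyc
        n_exceed += int((trans >= obs_trans).sum())
        n_tied += int((trans == obs_trans).sum())
        done += m
    tie_u = float(rng.random()) if randomized else None
    return PermutationResult.from_counts(
        observed=obs_trans / n_resolved_triads,
        n_perm=n_perm,
        n_exceed=n_exceed,
        seed=seed,
        sidedness="greater",
        n_tied=n_tied if randomized else None,
        tie_u=tie_u,
    )


def simulate_random_tournaments(
    n_lines: int, n_sims: int, seed: int = 0
) -> np.ndarray:
    """Cyclic-triad counts of random complete tournaments.

    Each simulation orients every edge of the complete graph on
    ``n_lines`` nodes uniformly at random; the return value is the number
    of cyclic triads per simulation.  Under this null each triad is
    cyclic with probability 1/4 and distinct triads are uncorrelated, so
    the mean is C(n,3)/4 and the variance 3*C(n,3)/16.
    """
    lines = [f"L{i:02d}" for i in range(n_lines)]
    pairs = list(combinations(range(n_lines), 2))
    eidx = {p: k for k, p in enumerate(pairs)}
    triads = np.array(
        [
            (eidx[(a, b)], eidx[(b, c)], eidx[(a, c)])
            for a, b, c in combinations(range(n_lines), 3)
        ],
        dtype=np.intp,
    )
    rng = perm_rng(seed)
    out = np.empty(n_sims, dtype=np.int64)
    chunk = max(1, min(n_sims, 20_000))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        bits = rng.integers(0, 2, size=(m, len(pairs)), dtype=np.uint8)
        out[done : done + m] = _count_cyclic(bits, triads)
        done += m
    return out


def stochastic_transitivity(
    net: ChoiceNetwork, ranking: Ranking | None = None
) -> StochasticTransitivityReport:
    """Classify the strength of transitivity over resolved transitive triads.

    For each transitive triad the edge directions give the order
    a > b > c; the three preference probabilities then satisfy weak
    transitivity by construction (asserted), and violations of the
    moderate and strong conditions are counted.  Cyclic and tie-containing
    triads are excluded and reported separately.
    """
    weak = moderate = strong = 0
    n_eligible = n_cyclic = n_tie = 0
    for a, b, c in combinations(sorted(net.lines), 3):
        wins = {}
        unresolved = False
        for x, y in ((a, b), (b, c), (a, c)):
            w = net.orientation(x, y)
            if w is None:
                unresolved = True
                break
            wins[(x, y)] = w
        if unresolved:
            n_tie += 1
            continue
        outdeg = {l: sum(1 for w in wins.values() if w == l) for l in (a, b, c)}
        order = sorted((a, b, c), key=lambda l: -outdeg[l])
        if outdeg[order[0]] != 2 or outdeg[order[2]] != 0:
            n_cyclic += 1
            continue
        n_eligible += 1
        top, mid, bot = order

        def pref(x: str, y: str) -> float:
            return float(net.pref.loc[x, y])

        p_ab, p_bc, p_ac = pref(top, mid), pref(mid, bot), pref(top, bot)
        assert min(p_ab, p_bc, p_ac) >= 0.5, (
            "edge-consistent ordering implies weak transitivity"
        )
        if p_ac < min(p_ab, p_bc):
            moderate += 1
        if p_ac < max(p_ab, p_bc):
            strong += 1
    return StochasticTransitivityReport(
        n_eligible_triads=n_eligible,
        weak_violations=weak,
        moderate_violations=moderate,
        strong_violations=strong,
        n_cyclic=n_cyclic,
        n_with_tie=n_tie,
    )
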