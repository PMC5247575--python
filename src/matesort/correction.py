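"""Receptivity correction of a choice network.

Female receptivity is correlated with mating bias, so part of the
apparent male preference may be female-driven.  The correction regresses
the per-pair preference proportion on the pairwise receptivity-score
difference (ordinary least squares on the proportion scale; a logit
option is available), takes residuals — how much more or less a line was
preferred than receptivity alone predicts — and re-orients the network
from the residual signs.  The corrected network is then re-tested for
transitivity and correlated with the uncorrected preferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .network import ChoiceNetwork, cross_chooser_correlation
from .permutation import PermutationResult
from .transitivity import (
    TriadCensus,
    UndefinedTransitivityError,
    permutation_test_transitivity,
    t_tri,
    triad_census,
)
from .traits import _pair_table

__all__ = [
    "CorrectionResult",
    "fit_preference_on_receptivity",
    "corrected_network",
    "run_correction_pipeline",
]


@dataclass
class CorrectionResult:
    slope: float
    intercept: float
    pairs: pd.DataFrame  # line_i, line_j, preference, recept_diff, residual
    corrected: ChoiceNetwork
    census: TriadCensus | None
    t_tri: float | None
    perm: PermutationResult | None
    corr_with_uncorrected: PermutationResult


def fit_preference_on_receptivity(
    pairs: pd.DataFrame, scale: str = "linear"
) -> tuple[float, float, pd.DataFrame]:
    """OLS of per-pair preference on the receptivity-score difference.

    ``pairs`` needs columns ``preference`` and ``recept_diff``; rows with
    undefined preference are dropped.  On the (default) linear scale the
    residual is preference minus fitted value, machine-exact; the
    ``"logit"`` option fits on log-odds and returns residuals on that
    scale.
    """
    d = pairs.dropna(subset=["preference", "recept_diff"]).copy()
    if len(d) < 3:
        raise ValueError("need at least 3 pairs with defined preference")
    x = d["recept_diff"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in receptivity differences")
    y = d["preference"].to_numpy(dtype=float)
    if scale == "logit":
        y = logit(np.clip(y, 1e-6, 1 - 1e-6))
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    slope, intercept = np.polyfit(x, y, 1)
    d["fitted"] = intercept + slope * x
    d["residual"] = y - d["fitted"]
    return float(slope), float(intercept), d


def corrected_network(pairs: pd.DataFrame) -> ChoiceNetwork:
    """Re-orient a network from regression residuals.

    A positive residual orients the edge toward the first (canonical)
    line of the pair, negative toward the second, exactly zero is a tie.
    The corrected preference value stored is 0.5 + residual (clipped to
    [0, 1]), so a zero-slope fit leaves the network unchanged.
    """
    pref = {}
    for _, row in pairs.iterrows():
        p = float(np.clip(0.5 + row["residual"], 0.0, 1.0))
        if row["residual"] == 0.0:
            p = 0.5
        pref[(row["line_i"], row["line_j"])] = p
    return ChoiceNetwork.from_preferences(pref)


def run_correction_pipeline(
    net: ChoiceNetwork,
    receptivity_scores: pd.Series,
    n_perm: int = 100_000,
    seed: int = 0,
    n_perm_corr: int = 10_000,
    scale: str = "linear",
) -> CorrectionResult:
    """Fit, correct, re-census, re-test, and compare with the original.

    The corrected-vs-uncorrected preference correlation uses the same
    line-label permutation scheme as cross-chooser comparisons.
    """
    table = _pair_table(net, receptivity_scores).rename(columns={"trait_diff": "recept_diff"})
    slope, intercept, pairs = fit_preference_on_receptivity(table, scale=scale)
    corr_net = corrected_network(pairs)

    census = ttri = perm = None
    try:
        census = triad_census(corr_net)
        ttri = t_tri(census)
        perm = permutation_test_transitivity(corr_net, n_perm=n_perm, seed=seed)
    except UndefinedTransitivityError:
        pass

    # restrict the uncorrected network to the same line set before comparing
    base = net.subset(corr_net.lines)
    corr_vs_unc, _ = cross_chooser_correlation(
        base, corr_net, n_perm=n_perm_corr, seed=seed + 1
    )
    return CorrectionResult(
        slope=slope,
        intercept=intercept,
        pairs=pairs.reset_index(drop=True),
        corrected=corr_net,
        census=census,
        t_tri=ttri,
        perm=perm,
        corr_with_uncorrected=corr_vs_unc,
    )
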