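"""Shared permutation-inference primitives.

Every randomization test in the package reports its result through
:class:`PermutationResult`, with the add-one p-value convention
``p = (n_exceed + 1) / (n_perm + 1)``.  With 100,000 replicates and zero
exceedances this floors at 1/100,001, matching the smallest p a
direction-randomization test of that size can report.

Replicate randomness always comes from numpy's Philox counter-based bit
generator keyed by the caller's seed, so identical ``(seed, n_perm)``
always yield identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PermutationResult", "perm_rng", "pearson_r", "pearson_r_many"]


def perm_rng(seed: int) -> np.random.Generator:
    """Counter-based generator used for all permutation replicates."""
    return np.random.Generator(np.random.Philox(key=seed))


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a randomization test.

    Attributes
    ----------
    observed : float
        The statistic computed on the un-permuted data.
    n_perm : int
        Number of random replicates drawn.
    n_exceed : int
        Replicates at least as extreme as ``observed`` (per ``sidedness``).
    p_value : float
        ``(n_exceed + 1) / (n_perm + 1)``.
    seed : int
        Seed of the Philox stream that produced the replicates.
    sidedness : str
        ``"two-sided"``, ``"greater"`` or ``"less"``.
    p_randomized : float, optional
        Tie-broken (randomized) p-value, exactly Uniform(0,1) under the
        null even when the statistic is discrete.  Only populated when a
        caller requests it for calibration diagnostics.
    """

    observed: float
    n_perm: int
    n_exceed: int
    p_value: float
    seed: int
    sidedness: str = "two-sided"
    p_randomized: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        expected = (self.n_exceed + 1) / (self.n_perm + 1)
        if not np.isclose(self.p_value, expected):
            raise ValueError(
                f"p_value {self.p_value} != (n_exceed+1)/(n_perm+1) = {expected}"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")

    @classmethod
    def from_counts(
        cls,
        observed: float,
        n_perm: int,
        n_exceed: int,
        seed: int,
        sidedness: str = "two-sided",
        n_tied: int | None = None,
        tie_u: float | None = None,
    ) -> "PermutationResult":
        """Build a result from exceedance counts.

        When ``n_tied`` (replicates exactly equal to the observed value)
        and a uniform draw ``tie_u`` are supplied, a randomized p-value is
        attached: ``p_rand = (n_strictly_greater + U * (n_tied + 1)) / (n_perm + 1)``.
        """
        p_rand = None
        if n_tied is not None and tie_u is not None:
            n_greater = n_exceed - n_tied
            p_rand = (n_greater + tie_u * (n_tied + 1)) / (n_perm + 1)
        return cls(
            observed=float(observed),
            n_perm=int(n_perm),
            n_exceed=int(n_exceed),
            p_value=(n_exceed + 1) / (n_perm + 1),
            seed=int(seed),
            sidedness=sidedness,
            p_randomized=p_rand,
        )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; NaN-free inputs expected."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("zero variance in one of the correlated variables")
    return float((xc @ yc) / denom)


def pearson_r_many(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of each row of ``X`` with ``y``.

    Rows with zero variance come back as NaN (callers treat them as
    non-exceeding).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / denom
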