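"""Offspring production and its link to mate preference.

Offspring counts per mated female are overdispersed with an excess of
zero vials (~10% of females), so line effects are modelled with a
zero-inflated negative binomial: a logit-intercept zero component mixed
with an NB2 count component carrying female-line and male-line fixed
effects (log link).  Line effects are tested by likelihood ratio against
the model without the female-line factor.  Outlying lines in trait-trait
relationships are screened with a Bonferroni outlier test on externally
studentized OLS residuals, and the preference-productivity correlation is
reported with and without any flagged outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .network import ChoiceNetwork
from .traits import PairwiseAssociation, preference_trait_correlation

__all__ = [
    "ZinbFit",
    "ConvergenceError",
    "fit_zinb",
    "lrt_line_effect",
    "bonferroni_outlier",
    "productivity_preference_correlation",
]


class ConvergenceError(RuntimeError):
    """A maximum-likelihood fit failed to converge."""


@dataclass
class ZinbFit:
    """Fitted zero-inflated negative-binomial model."""

    params: pd.Series
    llf: float
    k_params: int
    converged: bool
    alpha: float | None  # NB dispersion (None for fixed-alpha GLM fits)
    infl_logit: float | None  # zero-inflation intercept on the logit scale
    model_desc: str
    result: object = field(repr=False, default=None)

    @property
    def zero_inflation_prob(self) -> float | None:
        if self.infl_logit is None:
            return None
        from scipy.special import expit

        return float(expit(self.infl_logit))


def _design(records: pd.DataFrame, include_line: bool) -> tuple[np.ndarray, list[str]]:
    parts = [np.ones((len(records), 1))]
    names = ["const"]
    if include_line:
        dummies = pd.get_dummies(records["line"], drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names += [f"line[{c}]" for c in dummies.columns]
    if "male_line" in records and records["male_line"].nunique() > 1:
        dummies = pd.get_dummies(records["male_line"], drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names += [f"male_line[{c}]" for c in dummies.columns]
    return np.hstack(parts), names


def fit_zinb(
    records: pd.DataFrame,
    include_line: bool = True,
    inflation: str = "intercept",
    alpha_fixed: float | None = None,
    seed: int = 0,
) -> ZinbFit:
    """Maximum-likelihood zero-inflated negative-binomial fit.

    ``records`` needs ``line``, ``count`` and optionally ``male_line``
    columns.  The count component (log link) carries the female-line and
    male-line factors; the zero-inflation component is intercept-only.
    Starting values are Poisson coefficients with a moment-based
    dispersion; on non-convergence the optimizer restarts from three
    jittered starts before raising.

    ``inflation="none"`` fits a plain negative-binomial GLM instead; with
    ``alpha_fixed`` the dispersion is held at that value (``alpha_fixed``
    near 0 recovers a Poisson fit).
    """
    counts = records["count"].to_numpy()
    if (counts < 0).any() or not np.issubdtype(np.asarray(counts).dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if include_line and records["line"].nunique() < 2:
        raise ValueError("need >= 2 lines for a line effect")
    X, names = _design(records, include_line)
    y = counts.astype(float)

    if inflation == "none":
        alpha = alpha_fixed if alpha_fixed is not None else 1.0
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha))
        res = model.fit()
        return ZinbFit(
            params=pd.Series(res.params, index=names),
            llf=float(res.llf),
            k_params=X.shape[1],
            converged=bool(res.converged),
            alpha=alpha,
            infl_logit=None,
            model_desc=f"NB-GLM(alpha={alpha})"
            + ("" if alpha_fixed is not None else " [alpha not estimated]"),
            result=res,
        )
    if inflation != "intercept":
        raise ValueError(f"unknown inflation spec {inflation!r}")

    exog_infl = np.ones((len(y), 1))
    model = sm.ZeroInflatedNegativeBinomialP(y, X, exog_infl=exog_infl, p=2)

    pois = sm.Poisson(y, X).fit(disp=0)
    mu = pois.predict()
    zero_frac = float((y == 0).mean())
    nb_zero = float(np.mean((1.0 + mu) ** -1))  # rough NB zero mass at alpha=1
    excess = np.clip(zero_frac - nb_zero, 0.01, 0.8)
    start = np.concatenate(
        [[np.log(excess / (1 - excess))], pois.params, [1.0]]
    )

    rng = np.random.default_rng(seed)
    last_err = None
    methods = ("bfgs", "nm", "bfgs", "nm", "nm")
    for attempt, method in enumerate(methods):
        sp = start if attempt == 0 else start + rng.normal(0, 0.2, len(start))
        try:
            import warnings

            with warnings.catch_warnings():
                # optimizer line searches routinely overflow exp(); harmless
                warnings.simplefilter("ignore", RuntimeWarning)
                res = model.fit(
                    start_params=sp, method=method,
                    maxiter=5000 if method == "nm" else 500, disp=0,
                )
            if res.mle_retvals.get("converged", False) and np.isfinite(res.llf):
                k_infl = 1
                return ZinbFit(
                    params=pd.Series(res.params[k_infl:-1], index=names),
                    llf=float(res.llf),
                    k_params=len(res.params),
                    converged=True,
                    alpha=float(res.params[-1]),
                    infl_logit=float(res.params[0]),
                    model_desc="ZINB(intercept-only inflation)",
                    result=res,
                )
            last_err = f"optimizer did not converge (attempt {attempt}, {method})"
        except Exception as exc:  # noqa: BLE001 - surfaced below with context
            last_err = f"{type(exc).__name__}: {exc}"
    raise ConvergenceError(
        f"ZINB fit failed after {len(methods)} starts: {last_err}"
    )


def lrt_line_effect(full: ZinbFit, reduced: ZinbFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the female-line effect.

    Returns (chi2, df, p) with df the parameter-count difference.  A
    materially negative statistic signals a convergence failure in one of
    the fits and raises.
    """
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        raise ConvergenceError(
            f"negative LRT statistic {stat:.3g}: full model fit worse than reduced"
        )
    stat = max(stat, 0.0)
    df = full.k_params - reduced.k_params
    if df <= 0:
        raise ValueError("reduced model must have fewer parameters than full")
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def bonferroni_outlier(
    y: pd.Series, x: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni outlier test on a line-mean linear model.

    Externally studentized residuals of OLS of y on x; the two-sided t
    tail probability is multiplied by the number of lines (capped at 1)
    and lines with adjusted p below ``alpha`` are flagged.
    """
    lines = [l for l in y.index if l in x.index]
    if len(lines) < 4:
        raise ValueError("need at least 4 lines for an outlier test")
    yv = y[lines].to_numpy(dtype=float)
    xv = sm.add_constant(x[lines].to_numpy(dtype=float))
    res = sm.OLS(yv, xv).fit()
    if res.mse_resid < 1e-10 * (np.var(yv) + 1.0):
        raise ValueError("zero residual variance: no outliers definable")
    test = np.asarray(res.outlier_test(method="bonf"))
    out = pd.DataFrame(
        {
            "line": lines,
            "student_resid": test[:, 0],
            "unadj_p": test[:, 1],
            "bonf_p": np.minimum(test[:, 2], 1.0),
        }
    )
    out["flagged"] = out["bonf_p"] < alpha
    return out


def productivity_preference_correlation(
    net: ChoiceNetwork,
    offspring_means: pd.Series,
    exclude: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, PairwiseAssociation]:
    """Preference-productivity correlation, with and without an outlier line.

    Returns ``{"all": ..., "excluding": ...}``; the second entry is only
    present when ``exclude`` names a line, whose pairs are removed from
    the network and whose trait value is dropped before re-running the
    permutation correlation.
    """
    out = {
        "all": preference_trait_correlation(
            net, offspring_means, n_perm=n_perm, seed=seed, trait_name="offspring_mean"
        )
    }
    if exclude is not None:
        if exclude not in net.lines:
            raise ValueError(f"cannot exclude unknown line {exclude!r}")
        keep = [l for l in net.lines if l != exclude]
        out["excluding"] = preference_trait_correlation(
            net.subset(keep),
            offspring_means.drop(exclude),
            n_perm=n_perm,
            seed=seed,
            trait_name="offspring_mean",
        )
    return out
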