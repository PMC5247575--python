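"""Synthetic study generator.

Emulates a two-female mate-choice study on isogenic fly lines: a single
latent quality per line is expressed redundantly through a visual and a
chemical cue channel; female receptivity (courtship-to-mating speed) and
offspring production load on the same quality; two repellent cuticular
hydrocarbons (peaks 9 and 10 of a 29-peak profile) load negatively on it;
body mass is unrelated to quality.  Choice trials follow a Bradley-Terry /
logistic model on perceived-attractiveness differences, with the female's
receptivity entering the chooser's score additively.

All generators take an explicit seed (defaulting to ``config.seed``) and
are reproducible: identical seeds give identical tables.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .config import CONDITIONS, SimConfig, ValidationError

__all__ = [
    "gen_lines",
    "gen_choice_trials",
    "gen_receptivity_observations",
    "gen_offspring_counts",
    "gen_proximity_trials",
    "perceived_attractiveness",
    "N_CHC_PEAKS",
    "gen_trait_individuals",
]

#: number of hydrocarbon peaks in the per-individual profile
N_CHC_PEAKS = 29

# linear map from the receptivity latent (standard normal scale) to the
# line-mean courtship-to-mating time in minutes: time = T0 - TSCALE * latent
_RECEPT_T0 = 60.0
_RECEPT_TSCALE = 20.0

# line-level CHC relative-abundance maps (latent is standard normal)
_CHC9_BASE, _CHC9_SCALE = 0.15, 0.04
_CHC10_BASE, _CHC10_SCALE = 0.12, 0.035

_MASS_MEAN_MG, _MASS_SD_MG = 1.0, 0.08
_OFFSPRING_LOG_BASE, _OFFSPRING_LOG_SCALE = 3.4, 0.5


def _rng(config: SimConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def _loaded_latent(
    z: np.ndarray, loading: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal latent with correlation ``loading`` on ``z``."""
    noise = rng.standard_normal(z.shape)
    return loading * z + np.sqrt(max(0.0, 1.0 - loading**2)) * noise


def gen_lines(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw one set of line phenotypes.

    Returns one row per line with columns ``line_id``, latent quality
    ``q``, the two cue channels ``visual_cue``/``chemical_cue``, the
    receptivity latent and line-mean courtship-to-mating time,
    ``chc9_rel``/``chc10_rel`` relative abundances, ``mass_mean`` (mg) and
    ``offspring_mean``.

    If ``config.outlier_line`` is set, that line's quality is forced to the
    bottom of the set and its offspring mean to the top, decoupling
    productivity from attractiveness.
    """
    rng = _rng(config, seed)
    n = config.n_lines
    q = rng.normal(0.0, config.latent_quality_sd, n)

    if config.outlier_line is not None:
        others = np.delete(q, config.outlier_line)
        q[config.outlier_line] = others.min() - 0.5 * max(config.latent_quality_sd, 1e-12)

    # standardize on the population scale so loadings are correlations
    z = q / config.latent_quality_sd if config.latent_quality_sd > 0 else np.zeros(n)

    visual = q + rng.normal(0.0, config.channel_noise_sd, n)
    chemical = q + rng.normal(0.0, config.channel_noise_sd, n)

    recept_latent = _loaded_latent(z, config.receptivity_loading, rng)
    receptivity_mean = np.clip(_RECEPT_T0 - _RECEPT_TSCALE * recept_latent, 2.0, None)

    chc9_latent = _loaded_latent(z, -config.chc_loading, rng)
    chc10_latent = _loaded_latent(z, -config.chc_loading, rng)
    chc9 = np.clip(_CHC9_BASE + _CHC9_SCALE * chc9_latent, 0.005, 0.45)
    chc10 = np.clip(_CHC10_BASE + _CHC10_SCALE * chc10_latent, 0.005, 0.45)

    mass = rng.normal(_MASS_MEAN_MG, _MASS_SD_MG, n)

    off_latent = _loaded_latent(z, config.productivity_loading, rng)
    offspring_mean = np.exp(_OFFSPRING_LOG_BASE + _OFFSPRING_LOG_SCALE * off_latent)

    if config.outlier_line is not None:
        others = np.delete(offspring_mean, config.outlier_line)
        offspring_mean[config.outlier_line] = 1.25 * others.max()

    lines = pd.DataFrame(
        {
            "line_id": [f"L{i:02d}" for i in range(n)],
            "q": q,
            "visual_cue": visual,
            "chemical_cue": chemical,
            "receptivity_latent": recept_latent,
            "receptivity_mean": receptivity_mean,
            "chc9_rel": chc9,
            "chc10_rel": chc10,
            "mass_mean": mass,
            "offspring_mean": offspring_mean,
        }
    )
    assert (lines["chc9_rel"] + lines["chc10_rel"] <= 1.0).all()
    assert (lines["receptivity_mean"] > 0).all()
    return lines


def _condition_weights(config: SimConfig, condition: str) -> tuple[float, float]:
    wv, wc = config.channel_weights
    if condition == "intact":
        return wv, wc
    if condition == "no_visual":
        return 0.0, wc
    if condition == "no_chemical":
        return wv, 0.0
    if condition == "neither":
        return 0.0, 0.0
    raise ValidationError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def perceived_attractiveness(
    lines: pd.DataFrame, condition: str, config: SimConfig
) -> np.ndarray:
    """Noise-free perceived signal per line under a sensory condition."""
    wv, wc = _condition_weights(config, condition)
    return wv * lines["visual_cue"].to_numpy() + wc * lines["chemical_cue"].to_numpy()


def gen_choice_trials(
    lines: pd.DataFrame,
    condition: str,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate two-female choice trials for every unordered line pair.

    Each trial introduces one male to two females (lines a < b in label
    order).  The probability that any mating occurs scales with the
    sensory weight available to the chooser, falling to
    ``detection_floor`` when both channels are blocked.  Conditional on
    mating, the chosen line follows a logistic (Bradley-Terry) model on
    the difference in per-trial perceived attractiveness plus the additive
    receptivity term.
    """
    if len(lines) < 2:
        raise ValidationError("need at least 2 lines for choice trials")
    wv, wc = _condition_weights(config, condition)
    w_avail = wv + wc
    rng = _rng(config, seed)

    ids = lines["line_id"].to_numpy()
    base = perceived_attractiveness(lines, condition, config)
    recept = config.receptivity_weight * lines["receptivity_latent"].to_numpy()

    pairs = list(combinations(range(len(lines)), 2))
    reps = config.n_reps_per_pair
    ia = np.repeat([p[0] for p in pairs], reps)
    ib = np.repeat([p[1] for p in pairs], reps)
    n_trials = len(ia)

    p_mate = config.detection_floor + (config.base_mating_rate - config.detection_floor) * w_avail
    mated = rng.random(n_trials) < p_mate

    a_hat_a = base[ia] + rng.normal(0.0, config.perception_noise_sd, n_trials)
    a_hat_b = base[ib] + rng.normal(0.0, config.perception_noise_sd, n_trials)
    diff = (a_hat_a + recept[ia]) - (a_hat_b + recept[ib])
    from scipy.special import expit

    p_a = expit(config.choice_steepness * diff)
    chose_a = rng.random(n_trials) < p_a

    mated_line = np.where(mated, np.where(chose_a, ids[ia], ids[ib]), "")
    return pd.DataFrame(
        {
            "trial_id": [
                f"{condition}-{ids[x]}-{ids[y]}-{k}"
                for (x, y), k in zip(
                    zip(ia, ib), np.tile(np.arange(reps), len(pairs))
                )
            ],
            "condition": condition,
            "line_a": ids[ia],
            "line_b": ids[ib],
            "mated_line": mated_line,
        }
    )


def gen_receptivity_observations(
    lines: pd.DataFrame,
    n_per_line: int,
    config: SimConfig,
    seed: int | None = None,
    male_line: str = "CS",
) -> pd.DataFrame:
    """Per-individual courtship-to-mating times, right-censored.

    Times are gamma-distributed around the line mean with coefficient of
    variation ``receptivity_cv`` (shape 1/cv^2, scale mean*cv^2): positive,
    mildly right-skewed waiting times whose line-mean estimator is
    unbiased.  Individuals whose drawn time exceeds ``censor_minutes``
    are recorded at the censoring limit with ``censored=True``.
    """
    if n_per_line < 1:
        raise ValidationError("n_per_line must be >= 1")
    rng = _rng(config, seed)
    cv = config.receptivity_cv
    rows = []
    for _, line in lines.iterrows():
        mult = (
            rng.gamma(1.0 / cv**2, cv**2, n_per_line)
            if cv > 0
            else np.ones(n_per_line)
        )
        times = line["receptivity_mean"] * mult
        cens = times > config.censor_minutes
        minutes = np.where(cens, config.censor_minutes, times)
        for k in range(n_per_line):
            rows.append(
                {
                    "line": line["line_id"],
                    "male_line": male_line,
                    "individual": f"{line['line_id']}-{male_line}-r{k}",
                    "minutes": minutes[k],
                    "censored": bool(cens[k]),
                }
            )
    return pd.DataFrame(rows)


def gen_offspring_counts(
    lines: pd.DataFrame,
    n_per_line: int,
    config: SimConfig,
    seed: int | None = None,
    male_lines: tuple[str, ...] = ("CS",),
    male_effects: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Zero-inflated negative-binomial offspring counts per female.

    With probability ``zero_inflation`` a female yields zero offspring
    regardless of her line; otherwise counts are negative binomial with
    the line's mean (scaled by a mild male-line effect) and size
    ``nb_dispersion``.
    """
    if n_per_line < 1:
        raise ValidationError("n_per_line must be >= 1")
    if config.nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be > 0")
    if male_effects is None:
        male_effects = tuple(1.0 - 0.15 * i for i in range(len(male_lines)))
    rng = _rng(config, seed)
    size = config.nb_dispersion
    rows = []
    for _, line in lines.iterrows():
        for ml, eff in zip(male_lines, male_effects):
            mean = line["offspring_mean"] * eff
            p_nb = size / (size + mean)
            counts = rng.negative_binomial(size, p_nb, n_per_line)
            inflated = rng.random(n_per_line) < config.zero_inflation
            counts = np.where(inflated, 0, counts)
            for k in range(n_per_line):
                rows.append(
                    {
                        "line": line["line_id"],
                        "male_line": ml,
                        "individual": f"{line['line_id']}-{ml}-o{k}",
                        "count": int(counts[k]),
                    }
                )
    return pd.DataFrame(rows)


def gen_proximity_trials(
    lines: pd.DataFrame,
    pair: tuple[str, str],
    n_trials: int,
    config: SimConfig,
    seed: int | None = None,
    dwell_concentration: float = 8.0,
) -> pd.DataFrame:
    """Dwell times of a male near two decapitated females.

    ``pair`` is (line_plus, line_minus) with line_plus the female expected
    to be more attractive.  Decapitated females show no behaviour, so the
    expected dwell fraction near line_plus is a logistic function of the
    cue-signal gap alone (no receptivity term).  A configurable fraction
    of trials has total dwell under the 50 s analysis filter.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = _rng(config, seed)
    by_id = lines.set_index("line_id")
    for lab in pair:
        if lab not in by_id.index:
            raise ValidationError(f"unknown line label {lab!r}")
    sig = {
        lab: (
            config.channel_weights[0] * by_id.at[lab, "visual_cue"]
            + config.channel_weights[1] * by_id.at[lab, "chemical_cue"]
        )
        for lab in pair
    }
    from scipy.special import expit

    gap = sig[pair[0]] - sig[pair[1]]
    f = float(expit(config.choice_steepness * gap))

    short = rng.random(n_trials) < config.short_trial_fraction
    total = np.where(short, rng.uniform(5.0, 49.0, n_trials), rng.uniform(60.0, 600.0, n_trials))
    if f <= 0.0:
        frac = np.zeros(n_trials)
    elif f >= 1.0:
        frac = np.ones(n_trials)
    else:
        frac = rng.beta(dwell_concentration * f, dwell_concentration * (1.0 - f), n_trials)
    t_plus = total * frac
    return pd.DataFrame(
        {
            "trial_id": [f"prox-{pair[0]}-{pair[1]}-{k}" for k in range(n_trials)],
            "line_plus": pair[0],
            "line_minus": pair[1],
            "t_plus_s": t_plus,
            "t_minus_s": total - t_plus,
            "replicate": ["r1" if k < n_trials // 2 else "r2" for k in range(n_trials)],
        }
    )


def gen_trait_individuals(
    lines: pd.DataFrame,
    n_per_line: int,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-individual mass and 29-peak CHC relative-abundance profiles.

    Individual profiles scatter around the line means; each individual's
    relative abundances are renormalized to sum to one across the
    analysed peaks, as peak areas over total analysed area.
    """
    if n_per_line < 1:
        raise ValidationError("n_per_line must be >= 1")
    rng = _rng(config, seed)
    # background profile over the remaining 27 peaks; each line gets its own
    # independent multiplicative variation so that compositional
    # renormalization does not make every background peak track quality
    bg = np.linspace(1.0, 0.2, N_CHC_PEAKS - 2)
    rows = []
    for _, line in lines.iterrows():
        bg_line = bg * rng.lognormal(0.0, 0.35, N_CHC_PEAKS - 2)
        rest_total = 1.0 - line["chc9_rel"] - line["chc10_rel"]
        base = np.empty(N_CHC_PEAKS)
        base[8] = line["chc9_rel"]
        base[9] = line["chc10_rel"]
        rest = rest_total * bg_line / bg_line.sum()
        base[:8] = rest[:8]
        base[10:] = rest[8:]
        for k in range(n_per_line):
            noisy = base * rng.lognormal(0.0, 0.15, N_CHC_PEAKS)
            noisy = noisy / noisy.sum()
            row = {
                "line": line["line_id"],
                "individual": f"{line['line_id']}-t{k}",
                "mass_mg": max(0.1, rng.normal(line["mass_mean"], 0.05)),
            }
            row.update({f"chc_{j + 1}": noisy[j] for j in range(N_CHC_PEAKS)})
            rows.append(row)
    return pd.DataFrame(rows)
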