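"""End-to-end orchestration: simulate -> network -> transitivity ->
associations -> correction -> proximity -> fitness.

Each stage communicates with the next only through the documented CSV/JSON
schemas; the machine-readable report embeds the schema version, a config
hash, and every seed used, so a rerun with the same config reproduces it
byte-for-byte (modulo the timestamp field).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .config import RunConfig, SimConfig
from .correction import run_correction_pipeline
from .fitness import (
    bonferroni_outlier,
    fit_zinb,
    lrt_line_effect,
    productivity_preference_correlation,
)
from .network import (
    build_win_matrix,
    copeland_ranking,
    cross_chooser_correlation,
    mating_rate,
    preferences_and_orientation,
)
from .proximity import (
    attractiveness_fractions,
    fishers_combined,
    replicate_homogeneity,
    wilcoxon_vs_half,
)
from .simulate import (
    gen_choice_trials,
    gen_lines,
    gen_offspring_counts,
    gen_proximity_trials,
    gen_receptivity_observations,
    gen_trait_individuals,
    perceived_attractiveness,
)
from .traits import (
    anova_mass,
    lrt_receptivity,
    pairwise_individual_differences,
    preference_pairdiff_correlation,
    preference_trait_correlation,
    receptivity_score,
    screen_chcs,
)
from .transitivity import (
    UndefinedTransitivityError,
    permutation_test_transitivity,
    stochastic_transitivity,
    t_tri,
    triad_census,
)

__all__ = ["simulate_study", "analyze", "run", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

log = logging.getLogger("matesort")

#: chooser conditions simulated and analysed end to end
SIM_CONDITIONS = ("intact", "no_visual", "no_chemical", "neither")


def _config_hash(cfg: RunConfig) -> str:
    d = cfg.to_dict()
    d.pop("outdir", None)  # where results land is not part of the science
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def simulate_study(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full set of study-shaped CSV inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim
    base = cfg.seed

    lines = gen_lines(sim, seed=base)
    lines.to_csv(outdir / "lines_truth.csv", index=False)

    trials = pd.concat(
        [
            gen_choice_trials(lines, cond, sim, seed=base + 100 + k)
            for k, cond in enumerate(SIM_CONDITIONS)
        ],
        ignore_index=True,
    )
    msio.write_trials(trials, outdir / "trials.csv")

    recept = gen_receptivity_observations(
        lines, cfg.n_receptivity_per_line, sim, seed=base + 200, male_line="CS"
    )
    recept.to_csv(outdir / "receptivity.csv", index=False)

    traits = gen_trait_individuals(lines, 16, sim, seed=base + 300)
    traits.to_csv(outdir / "traits.csv", index=False)

    offspring = gen_offspring_counts(
        lines, cfg.n_offspring_per_line, sim, seed=base + 400, male_lines=("CS", "ppk23")
    )
    offspring.to_csv(outdir / "offspring.csv", index=False)

    # proximity pairs: the most attractive lines vs lower-ranked rivals,
    # mirroring a subset of previously assayed combinations
    sig = perceived_attractiveness(lines, "intact", sim)
    order = np.argsort(-sig)
    ids = lines["line_id"].to_numpy()
    pairs = [
        (ids[order[i]], ids[order[-(i + 1)]]) for i in range(min(cfg.n_proximity_pairs, len(ids) // 2))
    ]
    prox = pd.concat(
        [
            gen_proximity_trials(lines, pair, cfg.n_proximity_trials, sim, seed=base + 500 + k)
            for k, pair in enumerate(pairs)
        ],
        ignore_index=True,
    )
    prox.to_csv(outdir / "proximity.csv", index=False)

    return {
        "trials": outdir / "trials.csv",
        "receptivity": outdir / "receptivity.csv",
        "traits": outdir / "traits.csv",
        "offspring": outdir / "offspring.csv",
        "proximity": outdir / "proximity.csv",
        "lines_truth": outdir / "lines_truth.csv",
    }


def _perm_to_dict(perm) -> dict:
    return {
        "observed": perm.observed,
        "n_perm": perm.n_perm,
        "n_exceed": perm.n_exceed,
        "p_value": perm.p_value,
        "seed": perm.seed,
        "sidedness": perm.sidedness,
    }


def _network_stage(cfg: RunConfig, trials: pd.DataFrame, outdir: Path) -> tuple[dict, dict]:
    nets = {}
    section: dict = {"conditions": {}, "mating_rates": mating_rate(trials).to_dict("records")}
    for cond in sorted(trials["condition"].unique()):
        wm = build_win_matrix(trials, condition=cond)
        net = preferences_and_orientation(wm)
        nets[cond] = net
        ranking = copeland_ranking(net)
        msio.write_network(net, outdir / f"network_{cond}.csv", wins=wm)
        msio.write_ranking(ranking, outdir / f"ranking_{cond}.csv")
        n_no_data = len(net.no_data)
        if n_no_data:
            log.info("condition %s: %d pairs with no matings", cond, n_no_data)
        section["conditions"][cond] = {
            "n_pairs": len(list(combinations(net.lines, 2))),
            "n_no_data_pairs": n_no_data,
            "ranking": ranking.table.to_dict("records"),
        }
    return section, nets


def _transitivity_stage(cfg: RunConfig, nets: dict, outdir: Path) -> dict:
    out = {}
    for cond, net in nets.items():
        entry: dict = {}
        try:
            census = triad_census(net)
            entry["census"] = {
                "n_transitive": census.n_transitive,
                "n_cyclic": census.n_cyclic,
                "n_with_tie": census.n_with_tie,
            }
            entry["t_tri"] = t_tri(census)
            perm = permutation_test_transitivity(
                net, n_perm=cfg.n_perm_transitivity, seed=cfg.seed + 10
            )
            entry["perm"] = _perm_to_dict(perm)
            st = stochastic_transitivity(net)
            entry["stochastic"] = {
                "n_eligible": st.n_eligible_triads,
                "moderate_violations": st.moderate_violations,
                "strong_violations": st.strong_violations,
                "moderate_fraction": st.fraction("moderate"),
                "strong_fraction": st.fraction("strong"),
            }
        except UndefinedTransitivityError as exc:
            entry["t_tri"] = None
            entry["undefined_reason"] = str(exc)
            log.info("condition %s: %s", cond, exc)
        out[cond] = entry
    with open(outdir / "transitivity.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _cross_chooser_stage(cfg: RunConfig, nets: dict) -> dict:
    out = {}
    ref = "intact"
    if ref not in nets:
        return out
    for cond, net in nets.items():
        if cond in (ref, "neither"):
            continue
        try:
            res, n_dropped = cross_chooser_correlation(
                nets[ref], net, n_perm=cfg.n_perm_correlation, seed=cfg.seed + 20
            )
            out[f"{ref}_vs_{cond}"] = {**_perm_to_dict(res), "n_dropped_pairs": n_dropped}
            if n_dropped:
                log.info("%s vs %s: dropped %d undefined pairs", ref, cond, n_dropped)
        except ValueError as exc:
            out[f"{ref}_vs_{cond}"] = {"error": str(exc)}
    return out


def _associations_stage(
    cfg: RunConfig,
    nets: dict,
    recept: pd.DataFrame,
    traits: pd.DataFrame,
    outdir: Path,
) -> dict:
    net = nets["intact"]
    out: dict = {}
    rows = []

    # female mass: ANOVA among lines, then pairwise-difference correlation
    f, (dfb, dfw), p = anova_mass(traits)
    out["mass_anova"] = {"F": f, "df": [dfb, dfw], "p": p}
    mass_means = traits.groupby("line")["mass_mg"].mean()
    assoc = preference_trait_correlation(
        net, mass_means, n_perm=cfg.n_perm_correlation, seed=cfg.seed + 30,
        trait_name="mass_mg",
    )
    out["mass"] = {"r": assoc.r, **_perm_to_dict(assoc.perm)}
    rows.append(("mass_mg", assoc))

    # hydrocarbon screen against the attractiveness ranking
    chc_cols = [c for c in traits.columns if c.startswith("chc_")]
    chc_means = traits.groupby("line")[chc_cols].mean()
    ranking = copeland_ranking(net)
    screen = screen_chcs(chc_means, ranking, threshold=0.5)
    out["chc_screen"] = screen[screen["selected"]].to_dict("records")
    for peak in screen[screen["selected"]]["peak"]:
        assoc = preference_trait_correlation(
            net, chc_means[peak], n_perm=cfg.n_perm_correlation,
            seed=cfg.seed + 31, trait_name=peak,
        )
        out[peak] = {"r": assoc.r, **_perm_to_dict(assoc.perm)}
        rows.append((peak, assoc))

    # receptivity: line-mean score from uncensored observations
    uncens = recept[~recept["censored"]]
    line_means = uncens.groupby("line")["minutes"].mean()
    line_means = line_means.reindex(sorted(net.lines))
    scores = receptivity_score(line_means)
    out["receptivity_score"] = scores.to_dict()
    assoc = preference_trait_correlation(
        net, scores, n_perm=cfg.n_perm_correlation, seed=cfg.seed + 32,
        trait_name="receptivity_score",
    )
    out["receptivity"] = {"r": assoc.r, **_perm_to_dict(assoc.perm)}
    rows.append(("receptivity_score", assoc))

    # individual-level randomization (censored enter at the 200-min max)
    diffs = pairwise_individual_differences(
        recept, list(net.lines), seed=cfg.seed + 33,
        censor_minutes=cfg.sim.censor_minutes,
    )
    assoc = preference_pairdiff_correlation(
        net, diffs, n_perm=cfg.n_perm_correlation, seed=cfg.seed + 34,
        trait_name="receptivity_individual_diff",
    )
    out["receptivity_individual"] = {"r": assoc.r, **_perm_to_dict(assoc.perm)}
    rows.append(("receptivity_individual_diff", assoc))

    # receptivity line-effect LRT on log times
    stat, df, p = lrt_receptivity(recept)
    out["receptivity_lrt"] = {"chi2": stat, "df": df, "p": p}

    table = pd.DataFrame(
        [
            {
                "trait": name,
                "r": a.r,
                "p": a.perm.p_value,
                "n_perm": a.perm.n_perm,
                "sidedness": a.perm.sidedness,
                "seed": a.perm.seed,
            }
            for name, a in rows
        ]
    )
    table.to_csv(outdir / "associations.csv", index=False)
    return out


def _correction_stage(cfg: RunConfig, nets: dict, assoc: dict, outdir: Path) -> dict:
    net = nets["intact"]
    scores = pd.Series(assoc["receptivity_score"])
    res = run_correction_pipeline(
        net, scores, n_perm=cfg.n_perm_transitivity, seed=cfg.seed + 40,
        n_perm_corr=cfg.n_perm_correlation,
    )
    msio.write_network(res.corrected, outdir / "corrected_network.csv")
    out = {
        "corrected": True,
        "slope": res.slope,
        "intercept": res.intercept,
        "t_tri": res.t_tri,
        "census": None
        if res.census is None
        else {
            "n_transitive": res.census.n_transitive,
            "n_cyclic": res.census.n_cyclic,
            "n_with_tie": res.census.n_with_tie,
        },
        "perm": None if res.perm is None else _perm_to_dict(res.perm),
        "corr_with_uncorrected": _perm_to_dict(res.corr_with_uncorrected),
    }
    with open(outdir / "corrected_transitivity.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def _proximity_stage(cfg: RunConfig, prox: pd.DataFrame, alpha: float) -> dict:
    out: dict = {"comparisons": {}}
    one_tailed = []
    for (lp, lm), grp in prox.groupby(["line_plus", "line_minus"]):
        kept, n_filtered = attractiveness_fractions(grp)
        if n_filtered:
            log.info("proximity %s vs %s: filtered %d short trials", lp, lm, n_filtered)
        entry: dict = {"n_trials": len(grp), "n_filtered": n_filtered,
                       "n_analysed": len(kept)}
        reps = {r: g["fraction_plus"].to_numpy() for r, g in kept.groupby("replicate")}
        if len(reps) == 2 and all(len(v) >= 2 for v in reps.values()):
            check = replicate_homogeneity(reps, alpha=alpha)
            entry["replicate_p"] = check.p_value
            entry["replicates_combined"] = check.combine
        stat2, p2 = wilcoxon_vs_half(kept["fraction_plus"], alternative="two-sided")
        stat1, p1 = wilcoxon_vs_half(kept["fraction_plus"], alternative="greater")
        entry.update(
            {
                "mean_fraction_plus": float(kept["fraction_plus"].mean()),
                "wilcoxon_two_sided_p": p2,
                "wilcoxon_one_tailed_p": p1,
            }
        )
        one_tailed.append(p1)
        out["comparisons"][f"{lp}_vs_{lm}"] = entry
    chi2, df, p = fishers_combined(one_tailed)
    out["fishers_combined"] = {"chi2": chi2, "df": df, "p": p}
    return out


def _fitness_stage(
    cfg: RunConfig, nets: dict, offspring: pd.DataFrame, assoc: dict, traits_chc9: pd.Series
) -> dict:
    net = nets["intact"]
    out: dict = {}
    full = fit_zinb(offspring, include_line=True, seed=cfg.seed + 50)
    reduced = fit_zinb(offspring, include_line=False, seed=cfg.seed + 50)
    stat, df, p = lrt_line_effect(full, reduced)
    out["zinb_lrt"] = {"chi2": stat, "df": df, "p": p,
                       "zero_inflation_prob": full.zero_inflation_prob,
                       "alpha": full.alpha}

    means = offspring.groupby("line")["count"].mean()
    scores = pd.Series(assoc["receptivity_score"])
    outlier_tables = {}
    flagged: set[str] = set()
    for name, x in (("receptivity_score", scores), ("chc_9", traits_chc9)):
        try:
            tab = bonferroni_outlier(means, x)
            outlier_tables[name] = tab.to_dict("records")
            flagged |= set(tab[tab["flagged"]]["line"])
        except ValueError as exc:
            outlier_tables[name] = {"error": str(exc)}
    out["outlier_tests"] = outlier_tables
    out["flagged_lines"] = sorted(flagged)

    exclude = sorted(flagged)[0] if flagged else None
    corr = productivity_preference_correlation(
        net, means, exclude=exclude, n_perm=cfg.n_perm_correlation, seed=cfg.seed + 51
    )
    out["preference_correlation"] = {
        k: {"r": v.r, **_perm_to_dict(v.perm)} for k, v in corr.items()
    }
    out["excluded_line"] = exclude
    return out


def analyze(cfg: RunConfig, indir: str | Path, outdir: str | Path | None = None) -> dict:
    """Run every analysis stage on CSV inputs under ``indir``."""
    indir = Path(indir)
    outdir = Path(outdir) if outdir is not None else indir
    outdir.mkdir(parents=True, exist_ok=True)

    trials = msio.read_trials(indir / "trials.csv")
    recept = msio.read_receptivity(indir / "receptivity.csv")
    traits = msio.read_traits(indir / "traits.csv")
    offspring = msio.read_offspring(indir / "offspring.csv")
    prox = msio.read_proximity(indir / "proximity.csv")

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    network_sec, nets = _network_stage(cfg, trials, outdir)
    report["network"] = network_sec
    report["transitivity"] = _transitivity_stage(cfg, nets, outdir)
    report["cross_chooser"] = _cross_chooser_stage(cfg, nets)
    report["associations"] = _associations_stage(cfg, nets, recept, traits, outdir)
    report["correction"] = _correction_stage(cfg, nets, report["associations"], outdir)
    report["proximity"] = _proximity_stage(cfg, prox, cfg.alpha)
    chc9 = traits.groupby("line")["chc_9"].mean()
    report["fitness"] = _fitness_stage(cfg, nets, offspring, report["associations"], chc9)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run(cfg: RunConfig) -> dict:
    """Simulate a study under ``cfg`` and analyse it end to end."""
    outdir = Path(cfg.outdir)
    simulate_study(cfg, outdir)
    return analyze(cfg, outdir)


def summarize(report: dict) -> str:
    """Human-readable digest of a run report."""
    lines = [f"matesort report (schema v{report['schema_version']}, "
             f"config {report['config_hash']}, seed {report['seed']})"]
    for cond, entry in report.get("transitivity", {}).items():
        if entry.get("t_tri") is None:
            lines.append(f"  {cond}: t_tri undefined ({entry.get('undefined_reason', '')})")
        else:
            lines.append(
                f"  {cond}: t_tri={entry['t_tri']:.3f} p={entry['perm']['p_value']:.2g}"
            )
    for key, entry in report.get("cross_chooser", {}).items():
        if "observed" in entry:
            lines.append(f"  {key}: r={entry['observed']:.3f} p={entry['p_value']:.2g}")
    assoc = report.get("associations", {})
    for name in ("mass", "receptivity", "receptivity_individual"):
        if name in assoc:
            lines.append(
                f"  {name}: r={assoc[name]['observed']:.3f} p={assoc[name]['p_value']:.2g}"
            )
    corr = report.get("correction", {})
    if corr.get("t_tri") is not None:
        lines.append(
            f"  corrected: t_tri={corr['t_tri']:.3f} p={corr['perm']['p_value']:.2g}"
        )
    fish = report.get("proximity", {}).get("fishers_combined")
    if fish:
        lines.append(
            f"  proximity Fisher: chi2={fish['chi2']:.1f} df={fish['df']} p={fish['p']:.2g}"
        )
    fit = report.get("fitness", {})
    if "zinb_lrt" in fit:
        z = fit["zinb_lrt"]
        lines.append(f"  offspring line effect: chi2={z['chi2']:.1f} df={z['df']} p={z['p']:.2g}")
    return "\n".join(lines)
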