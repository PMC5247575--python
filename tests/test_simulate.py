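"""Generator behaviour: loadings, limits, censoring, reproducibility."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from matesort.config import SimConfig, ValidationError
from matesort.simulate import (
    gen_choice_trials,
    gen_lines,
    gen_offspring_counts,
    gen_proximity_trials,
    gen_receptivity_observations,
    gen_trait_individuals,
)


def _corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestGenLines:
    def test_zero_loadings_leave_traits_independent_of_quality(self):
        cfg = SimConfig(receptivity_loading=0.0, chc_loading=0.0, productivity_loading=0.0)
        rs = []
        for s in range(400):
            lines = gen_lines(cfg, seed=s)
            rs.append(
                (
                    _corr(lines["q"], lines["receptivity_mean"]),
                    _corr(lines["q"], lines["chc9_rel"]),
                    _corr(lines["q"], np.log(lines["offspring_mean"])),
                )
            )
        means = np.mean(rs, axis=0)
        assert np.all(np.abs(means) < 0.05)

    def test_perfect_productivity_loading_is_monotone_in_quality(self):
        cfg = SimConfig(productivity_loading=1.0)
        lines = gen_lines(cfg, seed=7)
        order = lines.sort_values("q")
        assert order["offspring_mean"].is_monotonic_increasing

    def test_chc_loading_matches_configured_value(self):
        # Monte-Carlo estimate over replicate line sets vs the configured
        # (negative) loading of the repellent hydrocarbon on quality.
        cfg = SimConfig()
        rs = [
            _corr(lines["q"], lines["chc9_rel"])
            for lines in (gen_lines(cfg, seed=s) for s in range(2000))
        ]
        assert abs(np.mean(rs) - (-cfg.chc_loading)) < 0.05

    def test_mass_uncorrelated_with_quality(self):
        cfg = SimConfig()
        rs = [
            _corr(gen_lines(cfg, seed=s)["q"], gen_lines(cfg, seed=s)["mass_mean"])
            for s in range(300)
        ]
        assert abs(np.mean(rs)) < 0.06

    def test_outlier_line_decouples_productivity_from_quality(self):
        cfg = SimConfig(outlier_line=3)
        for s in range(20):
            lines = gen_lines(cfg, seed=s)
            q_rank = lines["q"].rank()
            off_rank = lines["offspring_mean"].rank()
            assert q_rank.iloc[3] <= len(lines) * 0.25
            assert off_rank.iloc[3] > len(lines) * 0.75

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_lines=2)
        with pytest.raises(ValidationError):
            SimConfig(chc_loading=1.5)
        with pytest.raises(ValidationError):
            SimConfig(channel_weights=(0.7, 0.7))


class TestChoiceTrials:
    def _identical_pair(self) -> pd.DataFrame:
        row = {
            "q": 0.0, "visual_cue": 0.3, "chemical_cue": 0.3,
            "receptivity_latent": 0.1, "receptivity_mean": 55.0,
            "chc9_rel": 0.15, "chc10_rel": 0.12, "mass_mean": 1.0,
            "offspring_mean": 30.0,
        }
        return pd.DataFrame([{"line_id": "A", **row}, {"line_id": "B", **row}])

    def test_identical_lines_split_evenly(self):
        cfg = SimConfig(n_lines=3, n_reps_per_pair=10_000)
        trials = gen_choice_trials(self._identical_pair(), "intact", cfg, seed=5)
        mated = trials[trials["mated_line"] != ""]
        prop_a = (mated["mated_line"] == "A").mean()
        assert abs(prop_a - 0.5) < 0.02

    def test_neither_condition_mates_at_detection_floor(self):
        cfg = SimConfig(n_lines=3, n_reps_per_pair=10_000, detection_floor=0.02)
        trials = gen_choice_trials(self._identical_pair(), "neither", cfg, seed=6)
        rate = (trials["mated_line"] != "").mean()
        assert abs(rate - 0.02) < 3 * np.sqrt(0.02 * 0.98 / len(trials))

    def test_zero_steepness_flattens_preferences(self):
        cfg = SimConfig(n_lines=3, n_reps_per_pair=4000, choice_steepness=0.0)
        lines = gen_lines(cfg, seed=3)
        trials = gen_choice_trials(lines, "intact", cfg, seed=4)
        mated = trials[trials["mated_line"] != ""]
        for (a, b), grp in mated.groupby(["line_a", "line_b"]):
            prop = (grp["mated_line"] == a).mean()
            assert abs(prop - 0.5) < 0.04

    def test_unknown_condition_rejected(self):
        cfg = SimConfig(n_lines=3)
        with pytest.raises(ValidationError, match="condition"):
            gen_choice_trials(gen_lines(cfg, seed=0), "anosmic", cfg)


class TestReceptivity:
    def test_slow_lines_are_fully_censored(self):
        cfg = SimConfig(n_lines=3, receptivity_cv=0.1)
        lines = gen_lines(cfg, seed=0)
        lines["receptivity_mean"] = 2000.0
        obs = gen_receptivity_observations(lines, 50, cfg, seed=1)
        assert obs["censored"].mean() > 0.99
        assert (obs.loc[obs["censored"], "minutes"] == cfg.censor_minutes).all()

    def test_zero_noise_gives_line_means_exactly(self):
        cfg = SimConfig(n_lines=3, receptivity_cv=0.0)
        lines = gen_lines(cfg, seed=2)
        obs = gen_receptivity_observations(lines, 5, cfg, seed=3)
        merged = obs.merge(lines, left_on="line", right_on="line_id")
        assert np.allclose(merged["minutes"], merged["receptivity_mean"])

    def test_line_mean_estimates_cover_truth(self):
        # ~95% nominal coverage of the 2-s.e. interval around the sample mean
        cfg = SimConfig(n_lines=3)
        lines = gen_lines(cfg, seed=4)
        hits = total = 0
        for s in range(400):
            obs = gen_receptivity_observations(lines, 20, cfg, seed=100 + s)
            obs = obs[~obs["censored"]]
            for _, line in lines.iterrows():
                m = obs.loc[obs["line"] == line["line_id"], "minutes"]
                se = m.std(ddof=1) / np.sqrt(len(m))
                hits += abs(m.mean() - line["receptivity_mean"]) <= 2 * se
                total += 1
        assert hits / total >= 0.93


class TestOffspring:
    def test_full_inflation_means_all_zero(self):
        cfg = SimConfig(n_lines=3, zero_inflation=1.0)
        counts = gen_offspring_counts(gen_lines(cfg, seed=0), 30, cfg, seed=1)
        assert (counts["count"] == 0).all()

    def test_poisson_limit_at_large_dispersion(self):
        cfg = SimConfig(n_lines=3, zero_inflation=0.0, nb_dispersion=1e7)
        lines = gen_lines(cfg, seed=2)
        counts = gen_offspring_counts(lines, 4000, cfg, seed=3)
        for line, grp in counts.groupby("line"):
            ratio = grp["count"].var() / grp["count"].mean()
            assert abs(ratio - 1.0) < 0.1

    def test_excess_zero_fraction_matches_config(self):
        cfg = SimConfig(n_lines=5, zero_inflation=0.10)
        lines = gen_lines(cfg, seed=4)
        counts = gen_offspring_counts(lines, 5000, cfg, seed=5)
        size = cfg.nb_dispersion
        # per-line structural NB zero probability
        nb_zero = np.mean(
            [
                (size / (size + m)) ** size
                for m in lines["offspring_mean"]
            ]
        )
        expected = 0.10 + 0.90 * nb_zero
        observed = (counts["count"] == 0).mean()
        assert abs(observed - expected) < 0.01


class TestProximity:
    def test_equal_signal_pair_splits_evenly(self):
        cfg = SimConfig(n_lines=3, short_trial_fraction=0.0)
        lines = gen_lines(cfg, seed=0)
        lines.loc[1, ["visual_cue", "chemical_cue"]] = lines.loc[
            0, ["visual_cue", "chemical_cue"]
        ].to_numpy()
        trials = gen_proximity_trials(lines, ("L00", "L01"), 4000, cfg, seed=1)
        frac = trials["t_plus_s"] / (trials["t_plus_s"] + trials["t_minus_s"])
        assert abs(frac.mean() - 0.5) < 0.02

    def test_infinite_steepness_concentrates_dwell(self):
        cfg = SimConfig(n_lines=3, choice_steepness=np.inf)
        lines = gen_lines(cfg, seed=2)
        # order the pair by perceived signal (cue channels carry line-level
        # noise, so the top-quality line need not carry the top signal)
        from matesort.simulate import perceived_attractiveness

        sig = perceived_attractiveness(lines, "intact", cfg)
        plus = lines["line_id"].iloc[int(np.argmax(sig))]
        minus = lines["line_id"].iloc[int(np.argmin(sig))]
        trials = gen_proximity_trials(lines, (plus, minus), 100, cfg, seed=3)
        assert (trials["t_minus_s"] == 0).all()

    def test_short_trial_fraction_matches_config(self):
        cfg = SimConfig(n_lines=3, short_trial_fraction=0.10)
        lines = gen_lines(cfg, seed=4)
        trials = gen_proximity_trials(lines, ("L00", "L01"), 10_000, cfg, seed=5)
        total = trials["t_plus_s"] + trials["t_minus_s"]
        short = (total < 50).mean()
        assert abs(short - 0.10) < 0.01


class TestReproducibility:
    def test_identical_seeds_give_identical_tables(self, small_config):
        lines = gen_lines(small_config, seed=11)
        for gen in (
            lambda s: gen_lines(small_config, seed=s),
            lambda s: gen_choice_trials(lines, "intact", small_config, seed=s),
            lambda s: gen_receptivity_observations(lines, 5, small_config, seed=s),
            lambda s: gen_offspring_counts(lines, 5, small_config, seed=s),
            lambda s: gen_proximity_trials(lines, ("L00", "L01"), 8, small_config, seed=s),
            lambda s: gen_trait_individuals(lines, 4, small_config, seed=s),
        ):
            pdt.assert_frame_equal(gen(42), gen(42))

    def test_chc_profiles_sum_to_one(self, small_config):
        lines = gen_lines(small_config, seed=1)
        traits = gen_trait_individuals(lines, 6, small_config, seed=2)
        chc = traits[[c for c in traits.columns if c.startswith("chc_")]]
        assert np.allclose(chc.sum(axis=1), 1.0, atol=1e-9)
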