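"""Trait summaries and trait-preference permutation inference."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from matesort.config import SimConfig
from matesort.network import ChoiceNetwork, build_win_matrix, copeland_ranking, preferences_and_orientation
from matesort.simulate import gen_choice_trials, gen_lines, gen_receptivity_observations
from matesort.traits import (
    anova_mass,
    individual_receptivity_differences,
    lrt_receptivity,
    pairwise_individual_differences,
    preference_pairdiff_correlation,
    preference_trait_correlation,
    receptivity_score,
    screen_chcs,
    sma_slope,
)

from conftest import net_from_prefs


def _logistic_net(trait: pd.Series, slope: float = 3.0) -> ChoiceNetwork:
    prefs = {}
    for a, b in combinations(sorted(trait.index), 2):
        prefs[(a, b)] = float(expit(slope * (trait[a] - trait[b])))
    return net_from_prefs(prefs)


class TestReceptivityScore:
    def test_max_minus_mean(self):
        means = pd.Series({"A": 10.0, "B": 30.0, "C": 50.0})
        assert receptivity_score(means).to_dict() == {"A": 40.0, "B": 20.0, "C": 0.0}

    def test_equal_means_give_zero_scores(self):
        means = pd.Series({"A": 25.0, "B": 25.0})
        assert (receptivity_score(means) == 0).all()

    def test_score_order_reverses_time_order(self):
        rng = np.random.default_rng(0)
        means = pd.Series(rng.uniform(10, 90, 8), index=[f"L{i}" for i in range(8)])
        scores = receptivity_score(means)
        assert (scores.rank() == means.rank(ascending=False)).all()

    def test_simulated_lines_reproduce_configured_rank_order(self):
        cfg = SimConfig(n_lines=8, receptivity_cv=0.1)
        lines = gen_lines(cfg, seed=1)
        obs = gen_receptivity_observations(lines, 40, cfg, seed=2)
        est = obs[~obs["censored"]].groupby("line")["minutes"].mean()
        scores = receptivity_score(est)
        truth = lines.set_index("line_id")["receptivity_mean"]
        rho = stats.spearmanr(scores[truth.index], -truth).statistic
        assert rho > 0.95


class TestPreferenceTraitCorrelation:
    def test_perfect_signal_hits_p_floor(self):
        rng = np.random.default_rng(1)
        trait = pd.Series(rng.normal(0, 1, 8), index=[f"L{i}" for i in range(8)])
        net = _logistic_net(trait)
        res = preference_trait_correlation(net, trait, n_perm=999, seed=0)
        assert res.r > 0.9
        assert res.perm.p_value <= 3 / 1000

    def test_sign_flip_negates_r_and_keeps_two_sided_p(self):
        rng = np.random.default_rng(2)
        trait = pd.Series(rng.normal(0, 1, 8), index=[f"L{i}" for i in range(8)])
        net = _logistic_net(trait, slope=1.0)
        a = preference_trait_correlation(net, trait, n_perm=500, seed=3)
        b = preference_trait_correlation(net, -trait, n_perm=500, seed=3)
        assert b.r == pytest.approx(-a.r)
        assert b.perm.p_value == a.perm.p_value

    def test_affine_trait_transform_is_exactly_invariant(self):
        rng = np.random.default_rng(3)
        trait = pd.Series(rng.normal(0, 1, 8), index=[f"L{i}" for i in range(8)])
        net = _logistic_net(trait, slope=1.0)
        a = preference_trait_correlation(net, trait, n_perm=500, seed=4)
        b = preference_trait_correlation(net, 3.0 * trait + 17.0, n_perm=500, seed=4)
        assert b.r == pytest.approx(a.r, abs=1e-12)
        assert b.perm.n_exceed == a.perm.n_exceed

    def test_constant_trait_rejected(self):
        trait = pd.Series(1.0, index=[f"L{i}" for i in range(6)])
        net = _logistic_net(pd.Series(np.arange(6.0), index=trait.index))
        with pytest.raises(ValueError, match="constant"):
            preference_trait_correlation(net, trait)

    def test_pair_table_has_all_pairs_before_filtering(self):
        rng = np.random.default_rng(4)
        trait = pd.Series(rng.normal(0, 1, 7), index=[f"L{i}" for i in range(7)])
        net = _logistic_net(trait)
        res = preference_trait_correlation(net, trait, n_perm=200, seed=5)
        assert len(res.pairs) + res.n_dropped_pairs == 21

    def test_null_p_values_uniform(self):
        # trait independent of preference: KS uniformity over simulated runs
        rng = np.random.default_rng(5)
        ps = []
        for k in range(500):
            trait = pd.Series(rng.normal(0, 1, 8), index=[f"L{i}" for i in range(8)])
            other = pd.Series(rng.normal(0, 1, 8), index=trait.index)
            net = _logistic_net(other, slope=2.0)
            res = preference_trait_correlation(net, trait, n_perm=199, seed=9000 + k)
            ps.append(res.perm.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestIndividualReceptivity:
    def _obs(self, line, times, censored=None):
        censored = censored or [False] * len(times)
        return pd.DataFrame(
            {"line": line, "individual": [f"{line}{i}" for i in range(len(times))],
             "minutes": times, "censored": censored}
        )

    def test_constant_lines_give_exact_difference(self):
        a = self._obs("A", [10.0] * 6)
        b = self._obs("B", [30.0] * 6)
        assert individual_receptivity_differences(a, b, seed=0) == -20.0

    def test_identical_distributions_average_to_zero(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(10, 90, 30)
        a = self._obs("A", vals)
        b = self._obs("B", vals.copy())
        diffs = [individual_receptivity_differences(a, b, seed=s) for s in range(1000)]
        assert abs(np.mean(diffs)) < 1.0

    def test_censored_individual_enters_at_maximum(self):
        a = self._obs("A", [150.0], censored=[True])
        b = self._obs("B", [50.0])
        assert individual_receptivity_differences(a, b, seed=0) == 200.0 - 50.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            individual_receptivity_differences(self._obs("A", []), self._obs("B", [1.0]))

    def test_pairdiff_correlation_recovers_receptivity_signal(self):
        cfg = SimConfig(n_lines=8)
        lines = gen_lines(cfg, seed=7)
        trials = gen_choice_trials(lines, "intact", cfg, seed=8)
        net = preferences_and_orientation(build_win_matrix(trials))
        obs = gen_receptivity_observations(lines, 20, cfg, seed=9)
        diffs = pairwise_individual_differences(obs, list(net.lines), seed=10)
        res = preference_pairdiff_correlation(net, diffs, n_perm=500, seed=11)
        # longer times for line i mean lower receptivity, hence less preference
        assert res.r < 0


class TestChcScreen:
    def _ranking(self, net):
        return copeland_ranking(net)

    def test_proportional_peak_selected_with_unit_r(self):
        trait = pd.Series(np.arange(6.0), index=[f"L{i}" for i in range(6)])
        net = _logistic_net(trait, slope=50.0)
        rk = self._ranking(net)
        chc = pd.DataFrame({"chc_1": rk.scores() * 0.01 + 0.1}, index=rk.scores().index)
        out = screen_chcs(chc, rk)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "selected"]

    def test_constant_peak_excluded_with_note(self):
        trait = pd.Series(np.arange(6.0), index=[f"L{i}" for i in range(6)])
        net = _logistic_net(trait, slope=50.0)
        rk = self._ranking(net)
        chc = pd.DataFrame({"chc_flat": [0.2] * 6}, index=rk.scores().index)
        out = screen_chcs(chc, rk)
        assert not out["selected"].any()
        assert out.loc[0, "note"] == "constant"

    def test_repellent_channel_detected_in_most_simulations(self):
        from matesort.simulate import gen_trait_individuals

        hits = 0
        n_sims = 60
        for s in range(n_sims):
            cfg = SimConfig(seed=s)
            lines = gen_lines(cfg, seed=s)
            trials = gen_choice_trials(lines, "intact", cfg, seed=1000 + s)
            net = preferences_and_orientation(build_win_matrix(trials))
            rk = copeland_ranking(net)
            traits = gen_trait_individuals(lines, 16, cfg, seed=2000 + s)
            chc_cols = [c for c in traits.columns if c.startswith("chc_")]
            means = traits.groupby("line")[chc_cols].mean()
            sel = set(screen_chcs(means, rk).query("selected")["peak"])
            hits += bool({"chc_9", "chc_10"} & sel)
        assert hits / n_sims >= 0.9


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, _, p = anova_mass({"A": [1.0, 1.0], "B": [1.0, 1.0]})
        assert f == 0.0 and p == 1.0

    def test_complete_separation_gives_infinite_f(self):
        f, (dfb, dfw), p = anova_mass({"A": [0.0, 0.0], "B": [1.0, 1.0]})
        assert np.isinf(f) and p == 0.0
        assert (dfb, dfw) == (1, 2)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(8)
        groups = {f"L{i}": rng.normal(i * 0.1, 1, 12) for i in range(5)}
        f, _, p = anova_mass(groups)
        ref = stats.f_oneway(*groups.values())
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(1000):
            groups = {f"L{i}": rng.normal(0, 1, 8) for i in range(5)}
            ps.append(anova_mass(groups)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLrtReceptivity:
    def test_line_effect_detected_with_correct_df(self):
        cfg = SimConfig(n_lines=9)
        lines = gen_lines(cfg, seed=10)
        obs = gen_receptivity_observations(lines, 20, cfg, seed=11)
        stat, df, p = lrt_receptivity(obs)
        assert df == 8
        assert stat > 0 and p < 0.05

    def test_null_gives_moderate_statistic(self):
        cfg = SimConfig(n_lines=6, receptivity_loading=0.0)
        lines = gen_lines(cfg, seed=12)
        lines["receptivity_mean"] = 60.0
        obs = gen_receptivity_observations(lines, 20, cfg, seed=13)
        stat, df, p = lrt_receptivity(obs)
        assert df == 5
        assert p > 0.001


class TestSma:
    def test_exact_doubling_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept = sma_slope(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)

    def test_standardized_data_has_unit_slope(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 50)
        y = 0.4 * x + rng.normal(0, 1, 50)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        slope, _ = sma_slope(xs, ys)
        assert abs(slope) == pytest.approx(1.0)

    def test_slope_squared_equals_ols_slope_ratio(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 2, 40)
        y = 1.5 * x + rng.normal(0, 3, 40)
        slope, _ = sma_slope(x, y)
        b_yx = np.polyfit(x, y, 1)[0]
        b_xy = np.polyfit(y, x, 1)[0]
        assert slope**2 == pytest.approx(b_yx / b_xy, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sma_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
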