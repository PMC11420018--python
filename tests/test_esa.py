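import numpy as np
import pytest

import ersnet as e
from ersnet.esa import SCENARIOS, ESAProfile, GibbsSettings
from conftest import make_mgm_net


def two_node_net(weight, means=(24.0, 0.9), sds=(8.0, 0.9), resid=(1.0, 0.9)):
    w = np.array([[0.0, weight], [weight, 0.0]])
    return make_mgm_net(
        ["suppression", "fatigue"],
        w,
        ["continuous_strategy", "ordinal_symptom"],
        means=means,
        sds=sds,
        resid_sd=resid,
    )


def chain_net(w_sa=0.3, w_ab=0.25):
    w = np.array(
        [
            [0.0, w_sa, 0.0],
            [w_sa, 0.0, w_ab],
            [0.0, w_ab, 0.0],
        ]
    )
    return make_mgm_net(
        ["suppression", "sympA", "sympB"],
        w,
        ["continuous_strategy", "ordinal_symptom", "ordinal_symptom"],
        means=[24.0, 0.9, 0.9],
        sds=[8.0, 0.9, 0.9],
        resid_sd=[1.0, 0.9, 0.9],
    )


SAMPLER = GibbsSettings(n_samples=30_000, burn_in=1_000, n_chains=20)


class TestGibbsSampler:
    def test_zero_edge_makes_symptom_independent_of_clamp(self):
        net = two_node_net(0.0)
        esa_lo = e.expected_symptom_activity(net, {"suppression": 8.0}, SAMPLER, seed=1)
        esa_hi = e.expected_symptom_activity(net, {"suppression": 40.0}, SAMPLER, seed=2)
        exact = e.exact_symptom_means(net, {"suppression": 24.0}).sum()
        assert esa_lo == pytest.approx(exact, abs=0.03)
        assert esa_hi == pytest.approx(exact, abs=0.03)

    def test_continuous_conditional_matches_closed_form(self):
        # all-continuous 2-node model: s | x ~ N(0.4 x, 1), clamp x = 2
        w = np.array([[0.0, 0.4], [0.4, 0.0]])
        net = make_mgm_net(
            ["x", "s"], w, ["continuous_strategy", "continuous_strategy"]
        )
        samples = e.gibbs_sample_conditional(net, {"x": 2.0}, SAMPLER, seed=3)
        assert samples["s"].mean() == pytest.approx(0.8, abs=0.02)

    def test_clamp_effect_propagates_only_through_chain(self):
        net = chain_net()
        lo = e.exact_symptom_means(net, {"suppression": 8.0})
        hi = e.exact_symptom_means(net, {"suppression": 40.0})
        assert hi["sympA"] > lo["sympA"]
        assert hi["sympB"] > lo["sympB"]
        # zeroing the sympA-sympB edge removes the downstream effect
        cut = chain_net(w_ab=0.0)
        lo2 = e.exact_symptom_means(cut, {"suppression": 8.0})
        hi2 = e.exact_symptom_means(cut, {"suppression": 40.0})
        assert hi2["sympB"] == pytest.approx(lo2["sympB"], abs=1e-9)

    def test_gibbs_matches_exact_enumeration(self):
        net = chain_net()
        for clamp_value, seed in ((8.0, 4), (24.0, 5), (40.0, 6)):
            clamp = {"suppression": clamp_value}
            exact = e.exact_symptom_means(net, clamp).sum()
            sampled = e.expected_symptom_activity(net, clamp, SAMPLER, seed=seed)
            assert sampled == pytest.approx(exact, abs=0.03)

    def test_deterministic_given_seed(self):
        net = chain_net()
        a = e.gibbs_sample_conditional(net, {"suppression": 20.0}, SAMPLER, seed=9)
        b = e.gibbs_sample_conditional(net, {"suppression": 20.0}, SAMPLER, seed=9)
        assert a.equals(b)

    def test_invalid_inputs(self):
        net = chain_net()
        with pytest.raises(ValueError, match="cannot be clamped"):
            e.gibbs_sample_conditional(net, {"sympA": 1.0})
        with pytest.raises(ValueError, match="outside"):
            e.gibbs_sample_conditional(net, {"suppression": 50.0})
        with pytest.raises(ValueError):
            GibbsSettings(n_samples=0)


class TestExpectedSymptomActivity:
    def test_esa_is_sum_of_symptom_means(self):
        net = chain_net()
        clamp = {"suppression": 24.0}
        samples = e.gibbs_sample_conditional(net, clamp, SAMPLER, seed=11)
        esa = e.expected_symptom_activity(net, clamp, SAMPLER, seed=11)
        assert esa == pytest.approx(samples[["sympA", "sympB"]].mean().sum())

    def test_positive_edge_gives_monotone_esa(self):
        net = two_node_net(0.3)
        lo = e.exact_symptom_means(net, {"suppression": 8.0}).sum()
        hi = e.exact_symptom_means(net, {"suppression": 40.0}).sum()
        assert hi > lo

    def test_esa_within_bounds(self, fitted_mgm):
        gs = GibbsSettings(n_samples=2_000, burn_in=200, n_chains=20)
        clamp = {s: float(SCENARIOS["maximum"][s]) for s in e.STRATEGIES}
        esa = e.expected_symptom_activity(fitted_mgm, clamp, gs, seed=0)
        assert 0.0 <= esa <= 48.0


class TestBaseline:
    def test_observed_baseline_is_sum_of_sample_means(self, default_data, fitted_mgm):
        gs = GibbsSettings(n_samples=2_000, burn_in=200, n_chains=20)
        symptoms = default_data.symptom_matrix()
        res = e.baseline_esa(symptoms, fitted_mgm, gs, seed=1)
        assert res.observed == pytest.approx(symptoms.mean().sum())
        # generator calibration keeps the baseline in a plausible band
        assert 12.0 < res.observed < 18.0
        assert res.discrepancy == pytest.approx(res.model_implied - res.observed)


class TestScenarioSweep:
    def test_scenario_background_values(self):
        assert SCENARIOS["minimum"] == {
            "suppression": 8,
            "engagement": 8,
            "reappraisal": 8,
            "rumination": 6,
            "arousal_control": 4,
            "distraction": 4,
        }
        assert SCENARIOS["median"] == {
            "suppression": 24,
            "engagement": 24,
            "reappraisal": 24,
            "rumination": 18,
            "arousal_control": 12,
            "distraction": 12,
        }
        assert SCENARIOS["maximum"] == {
            "suppression": 40,
            "engagement": 40,
            "reappraisal": 40,
            "rumination": 30,
            "arousal_control": 20,
            "distraction": 20,
        }

    @pytest.mark.parametrize(
        "strategy, n_points", [("suppression", 33), ("rumination", 25), ("distraction", 17)]
    )
    def test_sweep_grid_lengths(self, strategy, n_points):
        net = make_mgm_net(
            [strategy, "fatigue"],
            np.array([[0.0, 0.2], [0.2, 0.0]]),
            ["continuous_strategy", "ordinal_symptom"],
            means=[20.0, 0.9],
            sds=[6.0, 0.9],
            resid_sd=[1.0, 0.9],
        )
        gs = GibbsSettings(n_samples=200, burn_in=50, n_chains=10)
        profile = e.esa_scenario_sweep(net, strategy, "minimum", baseline=1.0, settings=gs)
        assert len(profile.grid) == n_points
        assert (profile.grid[0], profile.grid[-1]) == e.strategy_score_range(strategy)
        assert len(profile.esa_values) == n_points
        assert np.all(profile.esa_values >= 0) and np.all(profile.esa_values <= 48)

    def test_flat_profile_without_strategy_edges(self):
        net = two_node_net(0.0)
        gs = GibbsSettings(n_samples=20_000, burn_in=500, n_chains=20)
        profile = e.esa_scenario_sweep(net, "suppression", "median", baseline=1.0, settings=gs)
        assert np.ptp(profile.esa_values) < 0.05

    def test_unknown_strategy_or_scenario(self, fitted_mgm):
        with pytest.raises(ValueError, match="strategy"):
            e.esa_scenario_sweep(fitted_mgm, "meditation", "minimum", 14.0)
        with pytest.raises(ValueError, match="scenario"):
            e.esa_scenario_sweep(fitted_mgm, "rumination", "typical", 14.0)


class TestCrossingPoint:
    def test_crossing_examples(self):
        profile = ESAProfile(
            strategy="rumination",
            scenario="minimum",
            grid=np.array([6, 7, 8]),
            esa_values=np.array([14.0, 14.5, 15.0]),
            baseline_esa=14.6,
        )
        assert e.crossing_point(profile) == 8

    def test_profile_below_baseline_has_no_crossing(self):
        profile = ESAProfile(
            strategy="rumination",
            scenario="minimum",
            grid=np.array([6, 7, 8]),
            esa_values=np.array([14.0, 14.1, 14.2]),
            baseline_esa=14.6,
        )
        assert e.crossing_point(profile) is None

    def test_profile_above_baseline_crosses_at_grid_minimum(self):
        profile = ESAProfile(
            strategy="rumination",
            scenario="minimum",
            grid=np.array([6, 7, 8]),
            esa_values=np.array([15.0, 15.1, 15.2]),
            baseline_esa=14.6,
        )
        assert e.crossing_point(profile) == 6

    def test_strict_inequality_at_baseline(self):
        profile = ESAProfile(
            strategy="rumination",
            scenario="minimum",
            grid=np.array([6, 7]),
            esa_values=np.array([14.6, 14.7]),
            baseline_esa=14.6,
        )
        assert e.crossing_point(profile) == 7
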