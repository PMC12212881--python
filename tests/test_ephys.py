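import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peons.ephys import (
    adaptation_fit,
    buildup_fit,
    classify_peons,
    cluster_correlation_coeffs,
    group_bootstrap,
    layer_from_depth,
    omission_response,
    overlap_statistics,
    probability_correlation,
    selectivity_indices,
    split_trials,
    subsample_trials,
    tone_response,
)


class TestResponseStatistic:
    def test_no_spikes_gives_zero(self):
        assert omission_response(np.array([]), 1000.0) == 0.0

    def test_response_window_rate(self):
        # 3 spikes in [5, 120) ms after onset, none in the baseline
        spikes = np.array([1010.0, 1050.0, 1100.0])
        assert omission_response(spikes, 1000.0) == pytest.approx(3 / 0.115)

    def test_baseline_subtraction_can_go_negative(self):
        spikes = np.array([990.0, 1010.0, 1050.0, 1100.0])
        expected = 3 / 0.115 - 1 / 0.029
        assert omission_response(spikes, 1000.0) == pytest.approx(expected)
        assert expected == pytest.approx(-8.39, abs=0.01)

    def test_tone_response_uses_same_windows(self):
        spikes = 2000.0 + np.array([6.0, 20.0, 50.0, 80.0, 119.0])
        assert tone_response(spikes, 2000.0) == pytest.approx(5 / 0.115)

    def test_windows_are_half_open(self):
        # a spike exactly at onset+120 is outside the response window,
        # one exactly at onset+5 is inside
        assert omission_response(np.array([1120.0]), 1000.0) == 0.0
        assert omission_response(np.array([1005.0]), 1000.0) == pytest.approx(
            1 / 0.115
        )


class TestSplitsAndSubsampling:
    def test_fifty_trials_split_25_25(self):
        trials = pd.DataFrame({"t": range(50)})
        odd, even = split_trials(trials)
        assert len(odd) == 25 and len(even) == 25

    def test_single_trial(self):
        odd, even = split_trials(pd.DataFrame({"t": [7]}))
        assert len(odd) == 1 and len(even) == 0

    def test_alternation_by_position(self):
        odd, even = split_trials(pd.DataFrame({"t": [1, 2, 3, 4]}))
        assert odd["t"].tolist() == [1, 3]
        assert even["t"].tolist() == [2, 4]

    @pytest.mark.parametrize("n, k", [(100, 2), (200, 4), (150, 3)])
    def test_every_kth_subsampling(self, n, k):
        out = subsample_trials(pd.DataFrame({"t": range(n)}))
        assert len(out) == 50
        assert out["t"].tolist() == list(range(0, 50 * k, k))

    def test_subsampling_is_identity_at_or_below_target(self):
        trials = pd.DataFrame({"t": range(50)})
        assert subsample_trials(trials)["t"].tolist() == list(range(50))


class TestOverlap:
    def test_published_population_numbers(self):
        res = overlap_statistics(123, 145, 990)
        assert round(res.expected) == 18

    def test_empty_subset(self):
        assert overlap_statistics(40, 0, 100).expected == 0.0

    def test_half_and_half(self):
        assert overlap_statistics(10, 10, 20).expected == pytest.approx(5.0)

    def test_expected_matches_exhaustive_hypergeometric_mean(self):
        # independent oracle: sum_k k * P(K = k) from binomial coefficients
        for n_total in range(1, 13):
            for n1 in range(n_total + 1):
                for n2 in range(n_total + 1):
                    mean = sum(
                        k
                        * math.comb(n1, k)
                        * math.comb(n_total - n1, n2 - k)
                        / math.comb(n_total, n2)
                        for k in range(max(0, n1 + n2 - n_total), min(n1, n2) + 1)
                    )
                    got = overlap_statistics(n1, n2, n_total).expected
                    assert got == pytest.approx(mean, abs=1e-12)

    def test_upper_tail_p(self):
        res = overlap_statistics(123, 145, 990, n_overlap=61)
        assert res.p_value < 1e-3

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            overlap_statistics(0, 0, 0)


class TestFits:
    def test_logistic_roundtrip_from_printed_parameters(self):
        a, b, c = 4.95, 0.012, 223.28
        pos = np.arange(1000)
        resp = a / (1 + np.exp(-b * (pos - c)))
        fit = buildup_fit(resp, pos, bin_width=50)
        assert fit.converged
        for got, true in zip(fit.params, (a, b, c)):
            assert abs(got - true) / true < 0.01
        assert fit.r_squared > 0.999

    def test_logistic_midpoint_identity(self):
        a, b, c = 4.95, 0.012, 223.28
        pos = np.arange(1000)
        fit = buildup_fit(a / (1 + np.exp(-b * (pos - c))), pos)
        af, bf, cf = fit.params
        assert af / (1 + np.exp(-bf * (cf - cf))) == pytest.approx(af / 2)

    def test_exponential_roundtrip_from_printed_parameters(self):
        d, e, f = 2.91, 396.36, 2.25
        n = np.arange(1, 51, dtype=float)
        resp = d + e * np.exp(-f * n)
        assert resp[0] == pytest.approx(41.78 + 2.91, abs=0.02)  # FR(1) ~ 44.68
        fit = adaptation_fit(resp, n)
        assert fit.converged
        for got, true in zip(fit.params, (d, e, f)):
            assert abs(got - true) / true < 0.01
        assert fit.r_squared > 0.999

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            buildup_fit(np.ones(10), np.arange(10), bin_width=50)


class TestSelectivityIndices:
    def test_symmetric_rates_give_zero(self):
        tsi, osi = selectivity_indices(5.0, 5.0, 2.0, 2.0)
        assert tsi == 0.0 and osi == 0.0

    def test_formula_arithmetic(self):
        tsi, _ = selectivity_indices(10.0, 5.0, 1.0, 1.0)
        assert tsi == pytest.approx(1 / 3)

    def test_boundary_when_one_rate_is_zero(self):
        tsi, _ = selectivity_indices(10.0, 0.0, 1.0, 1.0)
        assert tsi == 1.0

    def test_undefined_when_both_rates_zero(self):
        tsi, osi = selectivity_indices(0.0, 0.0, 0.0, 0.0)
        assert tsi is None and osi is None

    @settings(deadline=None, max_examples=50)
    @given(
        t_op=st.floats(0.1, 100),
        t_onp=st.floats(0.1, 100),
        scale=st.floats(0.01, 100),
    )
    def test_invariant_under_uniform_rate_scaling(self, t_op, t_onp, scale):
        base, _ = selectivity_indices(t_op, t_onp, 1.0, 1.0)
        scaled, _ = selectivity_indices(scale * t_op, scale * t_onp, 1.0, 1.0)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestClustering:
    def test_two_well_separated_bumps(self):
        rng = np.random.default_rng(0)
        rhos = np.concatenate(
            [rng.normal(-0.05, 0.02, 150), rng.normal(0.5, 0.02, 60)]
        )
        k_opt, labels, wcss = cluster_correlation_coeffs(rhos, seed=1)
        assert k_opt == 2
        assert len(np.unique(labels)) == 2
        assert np.all(np.diff(wcss) <= 1e-9)

    def test_identical_values_collapse_to_one_cluster(self):
        k_opt, labels, _ = cluster_correlation_coeffs(np.zeros(30), seed=1)
        assert k_opt == 1

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            cluster_correlation_coeffs(np.arange(5), k_max=10)


class TestProbabilityCorrelation:
    def test_proportional_responses_give_unit_rho(self):
        probs = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 10)
        rho, p, o_p, flagged = probability_correlation(2 * probs, probs)
        assert rho == pytest.approx(1.0)
        assert o_p == "A" and not flagged

    def test_anti_proportional_assigns_tone_b(self):
        probs = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 10)
        rho, p, o_p, _ = probability_correlation(-probs, probs)
        assert o_p == "B"
        assert rho == pytest.approx(1.0)

    def test_permuted_noise_usually_not_significant(self):
        rng = np.random.default_rng(2)
        probs = np.repeat([0.1, 0.3, 0.5, 0.7, 0.9], 20)
        rho, p, _, flagged = probability_correlation(rng.normal(size=100), probs)
        assert not flagged
        assert p > 0.05

    def test_tied_responses_flagged(self):
        rho, p, _, flagged = probability_correlation(
            np.ones(40), np.repeat([0.1, 0.9], 20)
        )
        assert flagged and rho == 0.0


class TestClassification:
    def test_planted_categories_on_crafted_recording(self, crafted_recording):
        table = classify_peons(crafted_recording, split="ODD").set_index("neuron_id")
        assert table.loc[0, "category"] == "peon"
        assert table.loc[0, "o_p_tone"] == "A"
        assert table.loc[1, "category"] == "correlation_only"
        assert table.loc[2, "category"] == "none"

    def test_splits_are_disjoint_and_exhaustive(self, crafted_recording):
        from peons.ephys import _omission_trials, split_events

        om = _omission_trials(crafted_recording)
        odd = split_events(om, "ODD")
        even = split_events(om, "EVEN")
        assert set(odd["onset_ms"]).isdisjoint(even["onset_ms"])
        assert len(odd) + len(even) == len(om)


class TestGroupBootstrap:
    def test_central_observation_has_p_near_one(self):
        # one third of each group flagged: observed equals the null mean
        groups = np.repeat(["x", "y"], 30)
        flags = np.zeros(60, bool)
        flags[:10] = True
        flags[30:40] = True
        out = group_bootstrap(flags, groups, n_boot=5000, seed=0)
        assert (out["p"] > 0.5).all()

    def test_total_concentration_reaches_resolution_floor(self):
        groups = np.repeat(["x", "y"], 50)
        flags = np.zeros(100, bool)
        flags[:25] = True  # all PEONs in group x
        out = group_bootstrap(flags, groups, n_boot=20000, seed=0).set_index("group")
        assert out.loc["x", "p"] < 1e-3

    def test_uniform_flags_rarely_significant(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(["a", "b", "c"], 40)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            flags = np.zeros(120, bool)
            flags[rng.choice(120, 20, replace=False)] = True
            out = group_bootstrap(flags, groups, n_boot=2000, seed=int(rng.integers(1 << 30)))
            rejections += int((out["p"] < 0.05).any())
        # 3 groups tested at 5 % each; expect ~14 % of repetitions to flag one
        assert rejections / n_rep < 0.35


def test_layer_band_assignment():
    assert layer_from_depth(100.0) == "supragranular"
    assert layer_from_depth(700.0) == "granular"
    assert layer_from_depth(1200.0) == "infragranular"
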