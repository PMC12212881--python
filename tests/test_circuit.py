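import math
from dataclasses import replace

import numpy as np
import pytest

from peons.circuit import (
    CircuitConfig,
    ConfigError,
    DEFAULT_RECEPTIVE_FIELD,
    NeuronParams,
    ROLES,
    adapted_strength,
    build_network,
    lateral_delay,
    lateral_weight,
    lif_first_spike_time,
    neuron_id,
    simulate,
    simulate_condition,
    update_prediction,
    verify_calibration,
)
from peons.model_eval import trial_response
from peons.stimuli import Condition, ToneSequence, generate_sequence


def _single_stream_config(**kw):
    return CircuitConfig(
        variant="none", n_streams=1, receptive_field={1: (1.0, 0.0)}, **kw
    )


class TestLateralLaws:
    @pytest.mark.parametrize("s1, s2, w", [(1, 2, 1.2), (1, 3, 0.3), (5, 1, 0.075)])
    def test_inverse_square_weight(self, s1, s2, w):
        assert lateral_weight(s1, s2) == pytest.approx(w)

    @pytest.mark.parametrize("s1, s2, d", [(1, 2, 5.0), (1, 5, 20.0), (4, 2, 10.0)])
    def test_linear_delay(self, s1, s2, d):
        assert lateral_delay(s1, s2) == pytest.approx(d)

    def test_self_connection_rejected(self):
        with pytest.raises(ConfigError):
            lateral_weight(3, 3)
        with pytest.raises(ConfigError):
            lateral_delay(3, 3)


class TestNetworkTopology:
    def test_no_lateral_variant_has_no_lateral_synapses(self):
        net = build_network(CircuitConfig(variant="none"))
        assert net.n_lateral == 0

    @pytest.mark.parametrize("variant", ["lateral_pe_to_pe", "lateral_i_to_pe"])
    def test_all_ordered_pairs_get_a_lateral_synapse(self, variant):
        net = build_network(CircuitConfig(variant=variant))
        assert net.n_lateral == 5 * 4
        pre_role = "PE+" if variant == "lateral_pe_to_pe" else "I"
        lateral = slice(len(net.pre) - net.n_lateral, None)
        assert all(r == ROLES.index(pre_role) for r in net.pre[lateral] % 6)
        assert all(r == ROLES.index("PE-") for r in net.post[lateral] % 6)

    def test_intra_module_wiring_is_the_four_path_motif(self):
        net = build_network(CircuitConfig(variant="none", n_streams=1))
        motif = {
            (net.pre[i] % 6, net.post[i] % 6, bool(net.is_inh[i]))
            for i in range(len(net.pre))
        }
        r = {name: i for i, name in enumerate(ROLES)}
        assert motif == {
            (r["I"], r["PE+"], False),
            (r["P"], r["I+"], False),
            (r["I+"], r["PE+"], True),
            (r["P"], r["PE-"], False),
            (r["I"], r["I-"], False),
            (r["I-"], r["PE-"], True),
        }
        assert net.n_neurons == 6

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            CircuitConfig(variant="ring")

    def test_default_receptive_field_matches_tonotopy(self):
        assert DEFAULT_RECEPTIVE_FIELD[2] == (1.0, 0.0)
        assert DEFAULT_RECEPTIVE_FIELD[4] == (0.0, 1.0)
        assert DEFAULT_RECEPTIVE_FIELD[3] == (0.5, 0.5)


class TestAdaptedStrength:
    def test_zero_probability_gives_full_strength(self):
        s_a, _ = adapted_strength(0.0, 0.3, 0.2)
        assert s_a == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pa, a, b, expected",
        [(0.5, 0.1, 0.1, 0.1061), (0.95, 0.5, 0.3, 0.4047)],
    )
    def test_decay_toward_base(self, pa, a, b, expected):
        s_a, _ = adapted_strength(pa, a, b)
        assert s_a == pytest.approx(expected, abs=1e-4)

    def test_symmetry_between_tones(self):
        s_a, s_b = adapted_strength(0.3, 0.2, 0.1)
        s_a2, s_b2 = adapted_strength(0.7, 0.2, 0.1)
        assert s_a == pytest.approx(s_b2)
        assert s_b == pytest.approx(s_a2)

    def test_invalid_adaptation_factor(self):
        with pytest.raises(ConfigError):
            adapted_strength(0.5, 0.0, 0.1)


class TestPredictionUpdate:
    def test_per_spike_impulses(self):
        assert update_prediction(0.0, 10, 0) == pytest.approx(0.01)
        assert update_prediction(0.5, 0, 10) == pytest.approx(0.497)

    def test_clipping(self):
        assert update_prediction(0.9999, 10, 0) == 1.0
        assert update_prediction(0.0001, 0, 5) == 0.0


class TestIntegrator:
    def test_constant_current_first_spike_matches_closed_form(self):
        cfg = _single_stream_config(stim_duration=50.0)
        seq = generate_sequence(Condition(1.0, 0.0, 0.0, n_items=1, seed=0))
        res = simulate(cfg, seq)
        spikes = res.spike_times(1, "I")
        t_star = lif_first_spike_time(0.2)
        assert t_star == pytest.approx(-30.0 * math.log(1 - 10.0 / 200.0))
        assert abs(spikes[0] - t_star) <= cfg.dt

    def test_interspike_intervals_respect_refractory_period(self):
        cfg = _single_stream_config(stim_duration=50.0)
        seq = generate_sequence(Condition(1.0, 0.0, 0.0, n_items=3, seed=0))
        res = simulate(cfg, seq)
        for role in ROLES:
            st = res.spike_times(1, role)
            if len(st) > 1:
                assert np.diff(st).min() >= cfg.neuron_params.t_ref

    def test_all_omission_sequence_is_silent(self):
        cfg = CircuitConfig()
        seq = generate_sequence(Condition(0.0, 0.0, 1.0, n_items=20, seed=0))
        res = simulate(cfg, seq)
        assert len(res.spike_time_ms) == 0
        assert np.all(res.p_traces == 0.0)

    def test_subthreshold_drive_never_spikes(self):
        # steady-state drive 8 mV < 10 mV threshold
        cfg = _single_stream_config(stim_amplitude=0.008, stim_duration=100.0)
        seq = generate_sequence(Condition(1.0, 0.0, 0.0, n_items=2, seed=0))
        res = simulate(cfg, seq)
        assert len(res.spike_times(1, "I")) == 0

    def test_p_traces_bounded(self):
        res = simulate_condition(CircuitConfig(), 0.9, n_items=60, seed=1)
        assert res.p_traces.min() >= 0.0
        assert res.p_traces.max() <= 1.0

    def test_zero_weight_laterals_reproduce_no_lateral_spike_for_spike(self):
        seq = generate_sequence(Condition(0.9, 0.05, 0.05, n_items=60, seed=4))
        res_zero = simulate(
            CircuitConfig(variant="lateral_pe_to_pe", lateral_base_weight=0.0), seq
        )
        res_none = simulate(CircuitConfig(variant="none"), seq)
        assert np.array_equal(res_zero.spike_neuron, res_none.spike_neuron)
        assert np.array_equal(res_zero.spike_time_ms, res_none.spike_time_ms)
        assert np.array_equal(res_zero.p_traces, res_none.p_traces)

    def test_halving_dt_changes_mean_peon_count_by_under_five_percent(self):
        counts = {}
        for dt in (0.1, 0.05):
            cfg = replace(CircuitConfig(), dt=dt)
            res = simulate_condition(cfg, 0.9, n_items=100, seed=3)
            counts[dt] = trial_response(res).mean()
        rel = abs(counts[0.05] - counts[0.1]) / counts[0.1]
        assert rel < 0.05


class TestCalibration:
    def test_default_weights_satisfy_operating_constraints(self):
        checks = verify_calibration()
        assert all(checks.values()), checks

    def test_established_prediction_states(self):
        # under 90 % A the prediction plateaus in the Tone-A streams with the
        # full-input stream highest, and the Tone-B streams stay near zero
        res = simulate_condition(CircuitConfig(), 0.9, n_items=500, seed=3)
        steady = res.p_traces[:, res.p_times_ms >= 25_000].mean(axis=1)
        assert steady[1] == steady.max()
        assert min(steady[0], steady[2]) > 0.05
        assert max(steady[3], steady[4]) < 0.05


def test_neuron_id_layout():
    assert neuron_id(1, "I") == 0
    assert neuron_id(2, "PE-") == 9
    with pytest.raises(ConfigError):
        neuron_id(6, "I")


def test_invalid_neuron_params():
    with pytest.raises(ConfigError):
        NeuronParams(v_thresh=0.0, v_reset=0.0)
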