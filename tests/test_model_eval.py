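import numpy as np
import pandas as pd
import pytest

from peons.circuit import CircuitConfig, SimulationResult, neuron_id
from peons.model_eval import (
    mean_prediction_energy,
    prediction_contrast,
    probability_sweep,
    steady_prediction,
    sweep_correlations,
    trial_response,
)
from peons.stimuli import Condition, ToneSequence


def _fake_result(spike_times, n_items=3, stream=2, role="PE-"):
    cond = Condition(0.0, 0.0, 1.0, n_items=n_items, soa=150.0, seed=0)
    seq = ToneSequence(
        items=np.array(["O"] * n_items, dtype="<U1"),
        onsets=np.arange(n_items, dtype=float) * 150.0,
        condition=cond,
    )
    nid = neuron_id(stream, role)
    times = np.asarray(spike_times, dtype=float)
    return SimulationResult(
        spike_neuron=np.full(len(times), nid),
        spike_time_ms=times,
        p_times_ms=np.array([0.0]),
        p_traces=np.zeros((5, 1)),
        sequence=seq,
        config=CircuitConfig(),
    )


class TestTrialResponse:
    def test_silent_neuron_counts_zero_everywhere(self):
        res = _fake_result([])
        assert trial_response(res).tolist() == [0, 0, 0]

    def test_interval_counting(self):
        # spikes at 3, 40 and 160 ms: two in trial 0, one in trial 1
        res = _fake_result([3.0, 40.0, 160.0])
        assert trial_response(res).tolist() == [2, 1, 0]

    def test_window_restricts_counting(self):
        res = _fake_result([3.0, 40.0, 160.0])
        assert trial_response(res, window=(0.0, 30.0)).tolist() == [1, 1, 0]

    def test_window_outside_trial_rejected(self):
        res = _fake_result([])
        with pytest.raises(ValueError):
            trial_response(res, window=(10.0, 200.0))


class TestSteadyPrediction:
    def test_constant_trace(self):
        t = np.arange(0, 75_001, 10.0)
        assert steady_prediction(t, np.full(len(t), 0.4)) == pytest.approx(0.4)

    def test_window_excludes_transient(self):
        t = np.arange(0, 75_001, 10.0)
        trace = np.where(t < 25_000, 0.0, 0.6)
        assert steady_prediction(t, trace) == pytest.approx(0.6, abs=1e-4)

    def test_short_trace_rejected(self):
        t = np.arange(0, 10_000, 10.0)
        with pytest.raises(ValueError):
            steady_prediction(t, np.zeros(len(t)))


class TestContrastAndEnergy:
    def test_equal_gains_give_zero_db(self):
        db, flagged = prediction_contrast(0.3, 0.3)
        assert db == pytest.approx(0.0)
        assert not flagged

    def test_tenfold_ratio_is_ten_db(self):
        db, _ = prediction_contrast(0.6, 0.06)
        assert db == pytest.approx(10.0)

    def test_zero_input_is_floored_and_flagged(self):
        db, flagged = prediction_contrast(0.0, 0.0)
        assert flagged
        assert np.isfinite(db)

    def test_mean_energy(self):
        assert mean_prediction_energy([0.5, 0.1, 0.1, 0.1, 0.2]) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            mean_prediction_energy([])


class TestProbabilitySweep:
    def test_single_point_grid_composition(self):
        sweep = probability_sweep(
            CircuitConfig(), grid=[0.9], n_items=500, seed=1
        )
        labels = sweep.records["label"].value_counts()
        assert labels["O"] == 25
        assert labels["A"] == 450
        assert labels["B"] == 25

    def test_negative_tone_b_probability_rejected(self):
        with pytest.raises(ValueError):
            probability_sweep(CircuitConfig(), grid=[0.99], seed=1)

    def test_bit_exact_reproducibility(self):
        a = probability_sweep(CircuitConfig(), grid=[0.5, 0.9], n_items=80, seed=9)
        b = probability_sweep(CircuitConfig(), grid=[0.5, 0.9], n_items=80, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.steady, b.steady)

    def test_adaptation_with_unit_base_factor_is_identity(self):
        # b = 1 collapses the adapted gains to 1 regardless of a
        from dataclasses import replace

        plain = probability_sweep(CircuitConfig(), grid=[0.9], n_items=80, seed=2)
        adapted = probability_sweep(
            replace(CircuitConfig(), adaptation=(0.5, 1.0)),
            grid=[0.9],
            n_items=80,
            seed=2,
        )
        pd.testing.assert_frame_equal(plain.records, adapted.records)


class TestSweepCorrelations:
    def test_constant_responses_flagged(self):
        sweep = probability_sweep(
            CircuitConfig(variant="none"), grid=[0.3, 0.6], n_items=40, seed=3
        )
        sweep.records["count"] = 0
        corr = sweep_correlations(sweep).set_index("label")
        assert corr["flagged"].all()
        assert (corr["rho"] == 0.0).all()

    def test_monotone_counts_give_positive_rho(self):
        sweep = probability_sweep(
            CircuitConfig(variant="none"), grid=[0.3, 0.6], n_items=40, seed=3
        )
        sweep.records["count"] = (sweep.records["prob_a"] * 10).astype(int)
        corr = sweep_correlations(sweep).set_index("label")
        assert corr.loc["O", "rho"] == pytest.approx(1.0)
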