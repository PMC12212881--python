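import numpy as np
import pandas as pd
import pytest

from peons.ephys import SpikeRecording
from peons.stimuli import EXPERIMENT_PROB_A
from peons.synthdata import GeneratorConfig, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """60-neuron synthetic recording with planted PEONs (shared, read-only)."""
    cfg = GeneratorConfig(n_neurons=60, seed=5)
    rec, truth = generate_recording(cfg)
    return rec, truth


def _spikes_for(neuron_id, onsets, n_resp, n_base):
    """Place n_resp spikes inside the response window and n_base inside the
    baseline window of each onset."""
    times = []
    for onset in onsets:
        times.extend(onset + 5.0 + 1.0 + np.arange(n_resp) * 2.0)
        times.extend(onset - 24.0 + 1.0 + np.arange(n_base) * 2.0)
    return pd.DataFrame(
        {"neuron_id": neuron_id, "spike_time_ms": sorted(times)}
    )


@pytest.fixture(scope="session")
def crafted_recording():
    """Deterministic 3-neuron recording with hand-placed spikes.

    Conditions 0..7 follow the experimental Prob(A) ladder.  Neuron 0 is a
    planted PEON (response-window spikes increase with Prob(A)); neuron 1 has
    probability-correlated but strictly negative responses (baseline spikes
    decrease with Prob(A)); neuron 2 is silent.
    """
    soa = 150.0
    n_items = 40
    n_omissions = 4
    cond_rows, ev_rows = [], []
    offset = 0.0
    order = sorted(EXPERIMENT_PROB_A)  # ascending Prob(A)
    for cid, pa in enumerate(order):
        pb = round(0.9 - pa, 10) if pa <= 0.9 else 0.0
        cond_rows.append({"condition_id": cid, "prob_a": pa, "prob_b": pb})
        for k in range(n_items):
            label = "O" if k % (n_items // n_omissions) == 2 else (
                "A" if k % 2 == 0 else "B"
            )
            ev_rows.append(
                {"condition_id": cid, "item_index": k, "label": label,
                 "onset_ms": offset + k * soa}
            )
        offset += n_items * soa + 5000.0
    events = pd.DataFrame(ev_rows)
    conditions = pd.DataFrame(cond_rows)
    om = events[events["label"] == "O"]
    frames = []
    for cid in conditions["condition_id"]:
        onsets = om.loc[om["condition_id"] == cid, "onset_ms"].to_numpy()
        frames.append(_spikes_for(0, onsets, n_resp=cid + 1, n_base=0))
        frames.append(_spikes_for(1, onsets, n_resp=0, n_base=8 - cid))
    spikes = pd.concat(frames, ignore_index=True)
    neurons = pd.DataFrame(
        {
            "neuron_id": [0, 1, 2],
            "depth_um": [300.0, 700.0, 1000.0],
            "layer": ["supragranular", "granular", "infragranular"],
            "field": ["A1", "VAF", "AAF"],
        }
    )
    return SpikeRecording(
        spikes=spikes, events=events, neurons=neurons, conditions=conditions
    )
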