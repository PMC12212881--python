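"""Multi-stream leaky integrate-and-fire predictive-coding circuit.

Each frequency-tuned *stream* is a module of six LIF neurons:

* ``I``  — sensory input neuron, driven by a 20-ms current pulse on tone trials;
* ``P``  — prediction neuron, driven by a 20-ms pulse of amplitude
  ``P_strength * 0.2`` uA on *every* trial (the pulse timing is assumed learned
  elsewhere; the circuit only adjusts its gain);
* ``PE+`` — positive prediction error: excited by I, inhibited by P via ``I+``;
* ``PE-`` — negative prediction error: excited by P, inhibited by I via ``I-``;
* ``I+``/``I-`` — the two inhibitory interneurons closing those paths.

``P_strength`` (one scalar per stream, clipped to [0, 1]) increases by 0.001
per PE+ spike and decreases by 0.0003 per PE- spike, so the prediction gain is
learned online from the error neurons' activity.

Streams interact through lateral excitatory synapses whose weight falls with
the squared stream distance (``base / d^2``) and whose delay grows linearly
(``5 d`` ms).  Three connectivity variants are supported: the full model with
PE+ -> PE- lateral connections, an alternative with I -> PE- lateral
connections, and a control with no lateral connections.

Membrane dynamics follow ``tau_m dV/dt = -V + Rm (Iexc - Iinh + Ipred + Istim)``
with Rm in MOhm, currents in uA and V in mV (so 0.2 uA drives toward 200 mV);
synaptic currents rise instantaneously by the synaptic weight on each delivered
spike and decay exponentially (tau 5 ms excitatory, 20 ms inhibitory).  All
state is advanced by forward Euler at ``dt`` (0.1 ms default); a spike is
emitted when V exceeds 10 mV, after which V is clamped at the reset value for
a 2-ms refractory period.  The model is fully deterministic: the only
randomness in any simulation is the stimulus sequence order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .stimuli import Condition, ToneSequence, generate_sequence

ROLES = ("I", "P", "PE+", "PE-", "I+", "I-")
ROLE_INDEX = {r: i for i, r in enumerate(ROLES)}
VARIANTS = ("lateral_pe_to_pe", "lateral_i_to_pe", "none")

_LABEL_CODE = {"A": 0, "B": 1, "O": 2}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NeuronParams:
    tau_m: float = 30.0      # ms
    r_m: float = 1.0         # MOhm
    v_thresh: float = 10.0   # mV
    v_reset: float = 0.0     # mV
    t_ref: float = 2.0       # ms

    def __post_init__(self) -> None:
        if min(self.tau_m, self.r_m, self.t_ref) <= 0 or self.v_thresh <= self.v_reset:
            raise ConfigError("invalid neuron parameters")


#: Intra-module synapses: (pre role, post role, weight uA, delay ms, inhibitory?).
#: Weights and delays are calibrated (see ``verify_calibration``), not copied:
#: the inhibitory disynaptic paths use short delays so feedforward inhibition
#: arrives before the direct excitatory drive on the error neurons.
DEFAULT_INTRA_TABLE: tuple[tuple[str, str, float, float, bool], ...] = (
    ("I", "PE+", 0.30, 6.0, False),
    ("P", "I+", 0.10, 1.0, False),
    ("I+", "PE+", 0.40, 1.0, True),
    ("P", "PE-", 0.15, 6.0, False),
    ("I", "I-", 0.12, 1.0, False),
    ("I-", "PE-", 0.28, 1.0, True),
)

#: stream (1-based) -> (gain for Tone A, gain for Tone B).  Stream 2 is tuned
#: to Tone A, stream 4 to Tone B; immediate neighbours get half-strength input.
DEFAULT_RECEPTIVE_FIELD: dict[int, tuple[float, float]] = {
    1: (0.5, 0.0),
    2: (1.0, 0.0),
    3: (0.5, 0.5),
    4: (0.0, 1.0),
    5: (0.0, 0.5),
}


def lateral_weight(s1: int, s2: int, base: float = 1.2) -> float:
    """Lateral synaptic weight ``base / (s2 - s1)^2`` (uA)."""
    if s1 == s2:
        raise ConfigError("no self-lateral connection (s1 == s2)")
    return base / float(s2 - s1) ** 2


def lateral_delay(s1: int, s2: int, per_step: float = 5.0) -> float:
    """Lateral synaptic delay ``per_step * |s2 - s1|`` (ms)."""
    if s1 == s2:
        raise ConfigError("no self-lateral connection (s1 == s2)")
    return per_step * abs(s2 - s1)


def adapted_strength(prob_a: float, a: float, b: float) -> tuple[float, float]:
    """Sensory-adaptation gains for the two tones as a function of Prob(A).

    ``S_A = (1 - b) exp(-Prob(A)/a) + b`` and symmetrically for B with
    ``1 - Prob(A)``: frequent exposure drives the sensory gain down toward the
    base firing factor ``b``.
    """
    if a <= 0:
        raise ConfigError("adaptation factor a must be > 0")
    if not 0 <= b <= 1:
        raise ConfigError("base firing factor b must be in [0, 1]")
    s_a = (1.0 - b) * math.exp(-prob_a / a) + b
    s_b = (1.0 - b) * math.exp(-(1.0 - prob_a) / a) + b
    return s_a, s_b


@dataclass(frozen=True)
class CircuitConfig:
    variant: str = "lateral_pe_to_pe"
    n_streams: int = 5
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    lateral_base_weight: float = 1.2     # uA at distance 1
    lateral_delay_per_step: float = 5.0  # ms per unit stream distance
    stim_amplitude: float = 0.2          # uA, full-strength sensory pulse
    stim_duration: float = 20.0          # ms
    pred_amplitude: float = 0.2          # uA multiplying P_strength
    p_increment: float = 0.001           # per PE+ spike
    p_decrement: float = 0.0003          # per PE- spike
    dt: float = 0.1                      # ms
    intra_table: tuple = DEFAULT_INTRA_TABLE
    adaptation: Optional[tuple[float, float]] = None   # (a, b) or None
    receptive_field: Optional[dict[int, tuple[float, float]]] = None
    p_record_stride: int = 10            # record P_strength every N steps

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.n_streams < 1 or self.dt <= 0:
            raise ConfigError("n_streams must be >= 1 and dt > 0")

    def rf(self) -> dict[int, tuple[float, float]]:
        if self.receptive_field is not None:
            return self.receptive_field
        return {
            s: DEFAULT_RECEPTIVE_FIELD.get(s, (0.0, 0.0))
            for s in range(1, self.n_streams + 1)
        }

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_streams": self.n_streams,
            "neuron_params": vars(self.neuron_params).copy(),
            "lateral_base_weight": self.lateral_base_weight,
            "lateral_delay_per_step": self.lateral_delay_per_step,
            "stim_amplitude": self.stim_amplitude,
            "stim_duration": self.stim_duration,
            "pred_amplitude": self.pred_amplitude,
            "p_increment": self.p_increment,
            "p_decrement": self.p_decrement,
            "dt": self.dt,
            "intra_table": [list(row) for row in self.intra_table],
            "adaptation": list(self.adaptation) if self.adaptation else None,
            "receptive_field": {str(k): list(v) for k, v in self.rf().items()},
        }


@dataclass
class Network:
    """Flattened synapse arrays for one configured circuit."""

    config: CircuitConfig
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray
    is_inh: np.ndarray

    @property
    def n_neurons(self) -> int:
        return 6 * self.config.n_streams

    @property
    def n_lateral(self) -> int:
        return len(self.pre) - 6 * self.config.n_streams


def neuron_id(stream: int, role: str, n_streams: int = 5) -> int:
    """Flat neuron index for 1-based ``stream`` and role name."""
    if not 1 <= stream <= n_streams:
        raise ConfigError(f"stream {stream} out of range")
    return (stream - 1) * 6 + ROLE_INDEX[role]


def build_network(config: CircuitConfig) -> Network:
    """Instantiate intra-module wiring plus variant-specific lateral synapses."""
    pre, post, w, d, inh = [], [], [], [], []
    ns = config.n_streams
    for s in range(1, ns + 1):
        for pre_role, post_role, weight, delay, is_inh in config.intra_table:
            pre.append(neuron_id(s, pre_role, ns))
            post.append(neuron_id(s, post_role, ns))
            w.append(weight)
            d.append(delay)
            inh.append(is_inh)
    if config.variant != "none":
        lateral_pre_role = "PE+" if config.variant == "lateral_pe_to_pe" else "I"
        for s1 in range(1, ns + 1):
            for s2 in range(1, ns + 1):
                if s1 == s2:
                    continue
                pre.append(neuron_id(s1, lateral_pre_role, ns))
                post.append(neuron_id(s2, "PE-", ns))
                w.append(lateral_weight(s1, s2, config.lateral_base_weight))
                d.append(lateral_delay(s1, s2, config.lateral_delay_per_step))
                inh.append(False)
    return Network(
        config=config,
        pre=np.asarray(pre, dtype=np.int64),
        post=np.asarray(post, dtype=np.int64),
        weight=np.asarray(w, dtype=np.float64),
        delay_ms=np.asarray(d, dtype=np.float64),
        is_inh=np.asarray(inh, dtype=np.bool_),
    )


@dataclass
class SimulationResult:
    """Spikes and prediction-gain traces from one deterministic simulation."""

    spike_neuron: np.ndarray      # flat neuron ids
    spike_time_ms: np.ndarray     # sorted within neuron by construction
    p_times_ms: np.ndarray        # sample times of the P_strength traces
    p_traces: np.ndarray          # (n_streams, len(p_times_ms)), in [0, 1]
    sequence: ToneSequence
    config: CircuitConfig

    def spike_times(self, stream: int, role: str) -> np.ndarray:
        nid = neuron_id(stream, role, self.config.n_streams)
        return self.spike_time_ms[self.spike_neuron == nid]

    def spikes_frame(self) -> pd.DataFrame:
        streams = self.spike_neuron // 6 + 1
        roles = np.array(ROLES)[self.spike_neuron % 6]
        return pd.DataFrame(
            {"stream": streams, "role": roles, "spike_time_ms": self.spike_time_ms}
        )

    def p_strength_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_ms": self.p_times_ms})
        for s in range(self.config.n_streams):
            out[f"stream_{s + 1}"] = self.p_traces[s]
        return out


@njit(cache=True)
def _run_kernel(
    n_neurons,
    n_steps,
    dt,
    tau_m,
    drive_gain,      # Rm * 1000: uA -> mV
    v_thresh,
    v_reset,
    ref_steps,
    tau_exc,
    tau_inh,
    syn_offsets,     # CSR offsets by presynaptic neuron, len n_neurons + 1
    syn_post,
    syn_w,
    syn_delay_steps,
    syn_is_inh,
    buf_len,
    stream_of,       # 0-based stream per neuron
    role_of,         # role index per neuron
    trial_onset_step,
    trial_label,     # 0 A, 1 B, 2 O
    soa_steps,
    pulse_steps,
    gain_a,          # per-stream stimulus amplitude for Tone A (uA)
    gain_b,
    pred_amp,
    p_inc,
    p_dec,
    p_init,          # per-stream initial P_strength
    rec_stride,
    max_spikes,
):
    n_streams = n_neurons // 6
    v = np.zeros(n_neurons)
    i_exc = np.zeros(n_neurons)
    i_inh = np.zeros(n_neurons)
    ref_until = np.full(n_neurons, -1, dtype=np.int64)
    buf_exc = np.zeros((buf_len, n_neurons))
    buf_inh = np.zeros((buf_len, n_neurons))
    p_strength = p_init.copy()

    n_rec = (n_steps + rec_stride - 1) // rec_stride
    p_trace = np.zeros((n_streams, n_rec))
    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0

    n_trials = len(trial_onset_step)
    trial_idx = 0

    decay_exc = dt / tau_exc
    decay_inh = dt / tau_inh

    for step in range(n_steps):
        # current trial and phase
        while trial_idx + 1 < n_trials and step >= trial_onset_step[trial_idx + 1]:
            trial_idx += 1
        in_pulse = (
            step >= trial_onset_step[trial_idx]
            and step - trial_onset_step[trial_idx] < pulse_steps
        )
        label = trial_label[trial_idx]

        # exponential decay of synaptic currents (forward Euler)
        for i in range(n_neurons):
            i_exc[i] -= decay_exc * i_exc[i]
            i_inh[i] -= decay_inh * i_inh[i]

        # delayed spike arrivals: instantaneous rise
        slot = step % buf_len
        for i in range(n_neurons):
            if buf_exc[slot, i] != 0.0:
                i_exc[i] += buf_exc[slot, i]
                buf_exc[slot, i] = 0.0
            if buf_inh[slot, i] != 0.0:
                i_inh[i] += buf_inh[slot, i]
                buf_inh[slot, i] = 0.0

        # membrane update and threshold crossing
        for i in range(n_neurons):
            if step < ref_until[i]:
                v[i] = v_reset
                continue
            i_net = i_exc[i] - i_inh[i]
            if in_pulse:
                role = role_of[i]
                s = stream_of[i]
                if role == 0:   # sensory input neuron
                    if label == 0:
                        i_net += gain_a[s]
                    elif label == 1:
                        i_net += gain_b[s]
                elif role == 1:  # prediction neuron
                    i_net += pred_amp * p_strength[s]
            v[i] += dt / tau_m * (-v[i] + drive_gain * i_net)
            if not np.isfinite(v[i]):
                return spike_neuron[:0], spike_step[:0], p_trace, -1
            if v[i] > v_thresh:
                v[i] = v_reset
                ref_until[i] = step + ref_steps
                if n_spikes < max_spikes:
                    spike_neuron[n_spikes] = i
                    spike_step[n_spikes] = step
                    n_spikes += 1
                # deliver to postsynaptic targets
                for k in range(syn_offsets[i], syn_offsets[i + 1]):
                    arrive = (step + syn_delay_steps[k]) % buf_len
                    if syn_is_inh[k]:
                        buf_inh[arrive, syn_post[k]] += syn_w[k]
                    else:
                        buf_exc[arrive, syn_post[k]] += syn_w[k]
                # online prediction-gain update
                role = role_of[i]
                s = stream_of[i]
                if role == 2:
                    p_strength[s] += p_inc
                    if p_strength[s] > 1.0:
                        p_strength[s] = 1.0
                elif role == 3:
                    p_strength[s] -= p_dec
                    if p_strength[s] < 0.0:
                        p_strength[s] = 0.0

        if step % rec_stride == 0:
            r = step // rec_stride
            for s in range(n_streams):
                p_trace[s, r] = p_strength[s]

    return spike_neuron[:n_spikes], spike_step[:n_spikes], p_trace, 0


def _csr_by_pre(net: Network) -> tuple[np.ndarray, ...]:
    order = np.argsort(net.pre, kind="stable")
    pre = net.pre[order]
    offsets = np.zeros(net.n_neurons + 1, dtype=np.int64)
    np.add.at(offsets[1:], pre, 1)
    offsets = np.cumsum(offsets)
    return (
        offsets,
        net.post[order],
        net.weight[order],
        net.delay_ms[order],
        net.is_inh[order],
    )


def simulate(
    config: CircuitConfig,
    seq: ToneSequence,
    p_init: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Run the circuit under a tone sequence; deterministic given inputs.

    ``p_init`` overrides the initial per-stream P_strength (default all zero,
    i.e. no prediction at sequence onset).
    """
    net = build_network(config)
    np_ = config.neuron_params
    dt = config.dt
    cond = seq.condition
    n_steps = int(round(cond.n_items * cond.soa / dt))

    offsets, post, w, delay_ms, is_inh = _csr_by_pre(net)
    delay_steps = np.maximum(np.round(delay_ms / dt).astype(np.int64), 1)
    buf_len = int(delay_steps.max()) + 1 if len(delay_steps) else 1

    stream_of = (np.arange(net.n_neurons, dtype=np.int64) // 6).astype(np.int64)
    role_of = (np.arange(net.n_neurons, dtype=np.int64) % 6).astype(np.int64)

    trial_onset_step = np.round(seq.onsets / dt).astype(np.int64)
    trial_label = np.array([_LABEL_CODE[l] for l in seq.items], dtype=np.int64)

    rf = config.rf()
    s_a = s_b = 1.0
    if config.adaptation is not None:
        s_a, s_b = adapted_strength(cond.prob_a, *config.adaptation)
    gain_a = np.array(
        [rf[s][0] * config.stim_amplitude * s_a for s in range(1, config.n_streams + 1)]
    )
    gain_b = np.array(
        [rf[s][1] * config.stim_amplitude * s_b for s in range(1, config.n_streams + 1)]
    )

    if p_init is None:
        p_init = np.zeros(config.n_streams)
    else:
        p_init = np.asarray(p_init, dtype=np.float64).copy()
        if p_init.shape != (config.n_streams,):
            raise ConfigError("p_init must have one value per stream")

    ref_steps = int(round(np_.t_ref / dt))
    max_spikes = net.n_neurons * (n_steps // max(ref_steps, 1) + 2)

    spike_neuron, spike_step, p_trace, status = _run_kernel(
        net.n_neurons,
        n_steps,
        dt,
        np_.tau_m,
        np_.r_m * 1000.0,
        np_.v_thresh,
        np_.v_reset,
        ref_steps,
        5.0,
        20.0,
        offsets,
        post,
        w,
        delay_steps,
        is_inh,
        buf_len,
        stream_of,
        role_of,
        trial_onset_step,
        trial_label,
        int(round(cond.soa / dt)),
        int(round(config.stim_duration / dt)),
        gain_a,
        gain_b,
        config.pred_amplitude,
        config.p_increment,
        config.p_decrement,
        p_init,
        config.p_record_stride,
        max_spikes,
    )
    if status != 0:
        raise FloatingPointError(
            "non-finite membrane potential during integration; "
            "check weights/dt for stability"
        )
    rec = np.arange(p_trace.shape[1]) * config.p_record_stride * dt
    return SimulationResult(
        spike_neuron=spike_neuron,
        spike_time_ms=spike_step * dt,
        p_times_ms=rec,
        p_traces=p_trace,
        sequence=seq,
        config=config,
    )


def update_prediction(
    p_strength: float,
    n_spikes_pe_plus: int,
    n_spikes_pe_minus: int,
    p_increment: float = 0.001,
    p_decrement: float = 0.0003,
) -> float:
    """Per-spike prediction-gain update, clipped to [0, 1].

    Each PE+ spike is an impulse raising the gain by ``p_increment``; each
    PE- spike lowers it by ``p_decrement``.
    """
    p = p_strength + p_increment * n_spikes_pe_plus - p_decrement * n_spikes_pe_minus
    return min(1.0, max(0.0, p))


def lif_first_spike_time(
    current_ua: float, params: NeuronParams = NeuronParams()
) -> float:
    """Closed-form first threshold crossing under constant current (ms).

    ``t* = -tau_m ln(1 - Vth / (Rm I))`` with ``Rm I`` in mV; infinite if the
    steady-state drive never reaches threshold.
    """
    drive = params.r_m * 1000.0 * current_ua
    if drive <= params.v_thresh:
        return math.inf
    return -params.tau_m * math.log(1.0 - params.v_thresh / drive)


def _probe(config: CircuitConfig, labels: list[str], p0: float) -> SimulationResult:
    cond = Condition(
        prob_a=labels.count("A") / len(labels),
        prob_b=labels.count("B") / len(labels),
        prob_omission=labels.count("O") / len(labels),
        n_items=len(labels),
        soa=150.0,
        seed=0,
    )
    seq = ToneSequence(
        items=np.array(labels, dtype="<U1"),
        onsets=np.arange(len(labels), dtype=float) * 150.0,
        condition=cond,
    )
    return simulate(config, seq, p_init=np.full(config.n_streams, p0))


def verify_calibration(config: Optional[CircuitConfig] = None) -> dict[str, bool]:
    """Assert the qualitative operating regime of the intra-module weights.

    Five constraints, each checked on a 3-trial probe simulation of the
    no-lateral circuit (except the last, a static weight comparison):

    i.   a full-strength unexpected tone (P_strength = 0) makes PE+ fire;
    ii.  an established prediction (P_strength = 1) silences PE+ on tone trials;
    iii. prediction input alone (omission, P_strength = 1) makes PE- fire;
    iv.  sensory input silences PE- during tone delivery despite full prediction;
    v.   lateral excitatory weights at stream distance 1 and 2 exceed the
         intra-module inhibitory weights onto the error neurons.
    """
    if config is None:
        config = CircuitConfig()
    base = replace(config, variant="none", adaptation=None)

    tone = _probe(base, ["A", "A", "A"], p0=0.0)
    ok_i = len(tone.spike_times(2, "PE+")) > 0

    tone_pred = _probe(base, ["A", "A", "A"], p0=1.0)
    ok_ii = len(tone_pred.spike_times(2, "PE+")) == 0
    ok_iv = len(tone_pred.spike_times(2, "PE-")) == 0

    omit_pred = _probe(base, ["O", "O", "O"], p0=1.0)
    ok_iii = len(omit_pred.spike_times(2, "PE-")) > 0

    inh_w = max(
        wt for _, post, wt, _, inh in config.intra_table if inh and post == "PE-"
    )
    ok_v = (
        lateral_weight(1, 2, config.lateral_base_weight) > inh_w
        and lateral_weight(1, 3, config.lateral_base_weight) > inh_w
    )
    return {
        "unexpected_tone_drives_pe_plus": ok_i,
        "prediction_silences_pe_plus": ok_ii,
        "prediction_alone_drives_pe_minus": ok_iii,
        "tone_silences_pe_minus": ok_iv,
        "lateral_exceeds_intra_inhibition": ok_v,
    }


def simulate_condition(
    config: CircuitConfig,
    prob_a: float,
    n_items: int = 500,
    seed: int = 0,
    prob_omission: float = 0.05,
) -> SimulationResult:
    """Convenience wrapper: generate the sequence for one condition and run it."""
    cond = Condition(
        prob_a=prob_a,
        prob_b=round(1.0 - prob_omission - prob_a, 10),
        prob_omission=prob_omission,
        n_items=n_items,
        seed=seed,
    )
    return simulate(config, generate_sequence(cond))
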