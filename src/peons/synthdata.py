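"""Synthetic spike recordings with planted ground truth.

Generates multi-neuron recordings that emulate the statistical structure the
analysis pipeline is designed to detect, without any real data: inhomogeneous
Poisson spike trains with

* a constant baseline rate (optionally slowly modulated);
* tone-evoked responses that adapt exponentially over repeated presentations
  of the same tone and scale down with that tone's probability (stimulus-
  specific adaptation / deviance structure);
* for planted PEONs, omission responses confined to the 5-120 ms window whose
  amplitude grows with the preferred tone's probability and builds up
  logistically over sequence position;
* per-neuron depth/layer/field metadata for the enrichment tests.

Poisson spiking (no refractoriness) keeps every expectation analytically
tractable; this is a deliberate simplification relative to real single units.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ephys import SpikeRecording, layer_from_depth
from .stimuli import Condition, child_seed, experiment_conditions, generate_sequence

FIELDS = ("A1", "VAF", "AAF")


@dataclass(frozen=True)
class GeneratorConfig:
    """Defaults chosen to echo the published response statistics: logistic
    buildup midpoint ~223 items with rate 0.012, fast exponential tone
    adaptation, and omission amplitudes that make a planted PEON clearly
    recoverable from 25 training trials per condition."""

    n_neurons: int = 200
    peon_fraction: float = 0.15
    baseline_rate: float = 5.0              # spikes/s
    tone_amplitude: float = 12.0            # steady evoked rate, spikes/s
    tone_adapt_amplitude: float = 40.0      # extra on the first presentations
    tone_adapt_rate: float = 2.25           # per presentation of that tone
    tone_prob_adapt_depth: float = 0.5      # steady amp scales 1 - depth*prob
    omission_amplitude_max: float = 20.0    # spikes/s at prob -> 1, late trials
    omission_probability_exponent: float = 1.0
    buildup_rate: float = 0.012             # logistic growth per item
    buildup_midpoint: float = 223.28        # sequence position
    response_latency_ms: float = 5.0
    response_duration_ms: float = 115.0
    kernel: str = "flat"                    # flat | alpha
    # Non-selective PEONs also respond to the other tone's omissions, but at a
    # clearly sub-dominant amplitude: they must remain probability encoders
    # for their preferred tone (the classification criterion they pass by
    # construction) while the secondary response stays detectable by the
    # selectivity test.
    selective_fraction: float = 0.75        # of PEONs; rest respond to both omissions
    nonselective_scale: float = 0.35
    field_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)
    baseline_mod_amplitude: float = 0.0     # fractional sinusoidal modulation
    baseline_mod_period_s: float = 30.0
    inter_condition_gap_ms: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.peon_fraction <= 1:
            raise ValueError("peon_fraction must be in [0, 1]")
        if min(self.baseline_rate, self.tone_amplitude,
               self.omission_amplitude_max) < 0:
            raise ValueError("rates must be non-negative")
        if self.kernel not in ("flat", "alpha"):
            raise ValueError("kernel must be 'flat' or 'alpha'")


@dataclass
class GroundTruth:
    """Planted per-neuron truth: PEON status, preferred tone, selectivity
    class and the planted response-curve parameters."""

    frame: pd.DataFrame
    config: GeneratorConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "neurons": self.frame.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _logistic(n: np.ndarray, b: float, c: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-b * (n - c)))


def _build_events(
    conditions: Sequence[Condition], gap_ms: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global event and condition tables; condition blocks are laid out
    back-to-back with a silent gap between them."""
    ev_frames = []
    cond_rows = []
    offset = 0.0
    for cid, cond in enumerate(conditions):
        seq = generate_sequence(cond)
        df = seq.to_frame(condition_id=cid)
        df["onset_ms"] = df["onset_ms"] + offset
        ev_frames.append(df)
        cond_rows.append(
            dict(condition_id=cid, prob_a=cond.prob_a, prob_b=cond.prob_b,
                 n_items=cond.n_items, start_ms=offset,
                 end_ms=offset + cond.duration_ms)
        )
        offset += cond.duration_ms + gap_ms
    events = pd.concat(ev_frames, ignore_index=True)[
        ["condition_id", "item_index", "label", "onset_ms"]
    ]
    return events, pd.DataFrame(cond_rows)


def _kernel_offsets(rng: np.random.Generator, n: int, cfg: GeneratorConfig):
    if cfg.kernel == "flat":
        return cfg.response_latency_ms + rng.uniform(
            0.0, cfg.response_duration_ms, size=n
        )
    # alpha-like shape: gamma(2, scale) truncated to the response window
    scale = cfg.response_duration_ms / 6.0
    t = rng.gamma(2.0, scale, size=n)
    return cfg.response_latency_ms + np.minimum(
        t, cfg.response_duration_ms * (1 - 1e-9)
    )


def generate_recording(
    config: GeneratorConfig,
    conditions: Optional[Sequence[Condition]] = None,
) -> tuple[SpikeRecording, GroundTruth]:
    """Draw a full synthetic recording plus its ground truth; deterministic
    given the config seed."""
    if conditions is None:
        conditions = experiment_conditions(seed=child_seed(config.seed, 901))
    events, cond_table = _build_events(conditions, config.inter_condition_gap_ms)
    total_end = float(cond_table["end_ms"].max())
    win_s = config.response_duration_ms / 1000.0

    meta_rng = np.random.default_rng(child_seed(config.seed, 902))
    n = config.n_neurons
    n_peons = int(round(config.peon_fraction * n))
    is_peon = np.zeros(n, dtype=bool)
    is_peon[meta_rng.choice(n, size=n_peons, replace=False)] = True
    o_p = np.where(meta_rng.random(n) < 0.5, "A", "B")
    selective = meta_rng.random(n) < config.selective_fraction
    depth = meta_rng.uniform(0.0, 1400.0, size=n)
    fields = meta_rng.choice(FIELDS, size=n, p=config.field_probs)
    gain_a = meta_rng.uniform(0.5, 1.5, size=n)
    gain_b = meta_rng.uniform(0.5, 1.5, size=n)

    # per-condition probability lookup aligned with the event table
    prob = {"A": {}, "B": {}}
    for _, row in cond_table.iterrows():
        prob["A"][row["condition_id"]] = row["prob_a"]
        prob["B"][row["condition_id"]] = row["prob_b"]

    ev_cid = events["condition_id"].to_numpy()
    ev_label = events["label"].to_numpy()
    ev_onset = events["onset_ms"].to_numpy()
    ev_pos = events["item_index"].to_numpy()

    # presentation index of each tone event within its condition
    pres_index = np.zeros(len(events), dtype=int)
    for cid in cond_table["condition_id"]:
        for tone in "AB":
            m = (ev_cid == cid) & (ev_label == tone)
            pres_index[m] = np.arange(m.sum())

    spike_frames = []
    for i in range(n):
        rng = np.random.default_rng(child_seed(config.seed, 903, i))
        # baseline: (optionally modulated) Poisson over the whole session
        n_base = rng.poisson(config.baseline_rate * total_end / 1000.0)
        base_t = rng.uniform(0.0, total_end, size=n_base)
        if config.baseline_mod_amplitude > 0:
            phase = 2 * np.pi * base_t / (config.baseline_mod_period_s * 1000.0)
            keep_p = (1 + config.baseline_mod_amplitude * np.sin(phase)) / (
                1 + config.baseline_mod_amplitude
            )
            base_t = base_t[rng.random(n_base) < keep_p]
        parts = [base_t]

        # tone-evoked responses with adaptation and probability scaling
        for tone, gain in (("A", gain_a[i]), ("B", gain_b[i])):
            m = ev_label == tone
            if not m.any():
                continue
            p_tone = np.array([prob[tone][c] for c in ev_cid[m]])
            steady = config.tone_amplitude * (
                1.0 - config.tone_prob_adapt_depth * p_tone
            )
            amp = gain * (
                steady
                + config.tone_adapt_amplitude
                * np.exp(-config.tone_adapt_rate * pres_index[m])
            )
            counts = rng.poisson(np.maximum(amp, 0.0) * win_s)
            rep_onsets = np.repeat(ev_onset[m], counts)
            parts.append(rep_onsets + _kernel_offsets(rng, len(rep_onsets), config))

        # planted omission responses (PEONs only)
        if is_peon[i]:
            m = ev_label == "O"
            p_op = np.array([prob[o_p[i]][c] for c in ev_cid[m]])
            amp = (
                config.omission_amplitude_max
                * p_op**config.omission_probability_exponent
                * _logistic(ev_pos[m], config.buildup_rate, config.buildup_midpoint)
            )
            if not selective[i]:
                o_np = "B" if o_p[i] == "A" else "A"
                p_onp = np.array([prob[o_np][c] for c in ev_cid[m]])
                amp = amp + (
                    config.nonselective_scale
                    * config.omission_amplitude_max
                    * p_onp**config.omission_probability_exponent
                    * _logistic(
                        ev_pos[m], config.buildup_rate, config.buildup_midpoint
                    )
                )
            counts = rng.poisson(amp * win_s)
            rep_onsets = np.repeat(ev_onset[m], counts)
            parts.append(rep_onsets + _kernel_offsets(rng, len(rep_onsets), config))

        t = np.sort(np.concatenate(parts))
        spike_frames.append(pd.DataFrame({"neuron_id": i, "spike_time_ms": t}))

    spikes = pd.concat(spike_frames, ignore_index=True)
    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "depth_um": depth,
            "layer": [layer_from_depth(d) for d in depth],
            "field": fields,
        }
    )
    truth = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "is_peon": is_peon,
            "o_p_tone": o_p,
            "selectivity": np.where(
                ~is_peon, "none", np.where(selective, "selective", "non_selective")
            ),
            "tone_class": "both",
            "gain_a": gain_a,
            "gain_b": gain_b,
            "depth_um": depth,
            "layer": neurons["layer"],
            "field": fields,
            "omission_amplitude_max": np.where(
                is_peon, config.omission_amplitude_max, 0.0
            ),
            "buildup_rate": config.buildup_rate,
            "buildup_midpoint": config.buildup_midpoint,
        }
    )
    rec = SpikeRecording(
        spikes=spikes,
        events=events,
        neurons=neurons,
        conditions=cond_table[["condition_id", "prob_a", "prob_b"]].copy(),
    )
    return rec, GroundTruth(frame=truth, config=config)


def null_recording(
    config: GeneratorConfig,
    conditions: Optional[Sequence[Condition]] = None,
) -> SpikeRecording:
    """Recording with tone kernels but no omission structure at all
    (``peon_fraction = 0``): the false-positive calibration input."""
    cfg = GeneratorConfig(**{**asdict(config), "peon_fraction": 0.0})
    rec, _ = generate_recording(cfg, conditions)
    return rec
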