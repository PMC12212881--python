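"""End-to-end reproduction pipelines and run manifests.

Two entry points mirror the study's two halves: ``reproduce_model_figures``
runs the connectivity-variant probability sweeps, the lateral-benefit
analyses and the sensory-adaptation model comparison; and
``reproduce_ephys_pipeline`` runs the full recording analysis (synthetic
recording -> split-half PEON classification -> overlap -> buildup/adaptation
fits -> selectivity -> laminar/areal bootstrap) and scores recovery against
the planted ground truth.  Every run writes a ``manifest.json`` (config hash,
seed, package version) next to its outputs so results are re-derivable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .circuit import CircuitConfig
from .ephys import (
    adaptation_fit,
    split_events,
    buildup_fit,
    classify_peons,
    group_bootstrap,
    overlap_statistics,
    population_tone_correlations,
    selectivity_classification,
    event_responses,
    _omission_trials,
    _tone_trials_split,
    STANDARD_PROB_MIN,
)
from .model_eval import (
    adaptation_sweep,
    benefit_analysis,
    correlation_sign_report,
    probability_sweep,
    sweep_correlations,
)
from .stimuli import child_seed, model_grid
from .synthdata import GeneratorConfig, generate_recording

log = logging.getLogger("peons")


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "config": json.loads(blob),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def reproduce_model_figures(
    out_dir: str | Path,
    seed: int = 0,
    config: Optional[CircuitConfig] = None,
    grid_step: float = 0.05,
    benefit_step: float = 0.01,
    variants: Sequence[str] = ("lateral_pe_to_pe", "lateral_i_to_pe", "none"),
    run_adaptation: bool = True,
    adaptation_grid_step: float = 0.19,
) -> dict:
    """Variant sweeps, correlation sign report, benefit and adaptation analyses.

    The adaptation comparison uses a coarse probability grid by default (the
    12 (a, b) combinations multiply the simulation count by 36); pass a finer
    ``adaptation_grid_step`` for the full layout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = CircuitConfig()
    grid = model_grid(step=grid_step)

    corr_frames = []
    record_frames = []
    for variant in variants:
        log.info("probability sweep: variant=%s", variant)
        cfg = replace(config, variant=variant)
        sweep = probability_sweep(cfg, grid=grid, seed=child_seed(seed, 1))
        corr_frames.append(sweep_correlations(sweep))
        rec = sweep.records.copy()
        rec.insert(0, "variant", variant)
        record_frames.append(rec)
    correlations = pd.concat(corr_frames, ignore_index=True)
    records = pd.concat(record_frames, ignore_index=True)
    signs = correlation_sign_report(correlations)

    log.info("benefit analysis (step=%.2f)", benefit_step)
    benefit = benefit_analysis(
        config, grid=model_grid(step=benefit_step), seed=child_seed(seed, 2)
    )

    records.to_csv(out / "sweep_records.csv", index=False)
    correlations.to_csv(out / "sweep_correlations.csv", index=False)
    signs.to_csv(out / "sign_report.csv", index=False)
    benefit.to_csv(out / "benefit.csv", index=False)

    result = {
        "correlations": correlations,
        "sign_report": signs,
        "benefit": benefit,
    }
    if run_adaptation:
        log.info("adaptation sweep")
        adapt = adaptation_sweep(
            config,
            grid=model_grid(step=adaptation_grid_step),
            variants=variants,
            seed=child_seed(seed, 3),
        )
        adapt.to_csv(out / "adaptation_sweep.csv", index=False)
        result["adaptation"] = adapt
    write_manifest(
        out,
        {
            "stage": "model_figures",
            "circuit": config.to_dict(),
            "grid_step": grid_step,
            "benefit_step": benefit_step,
            "variants": list(variants),
        },
        seed,
    )
    return result


def _pooled_buildup_inputs(rec, peons, split):
    """Omission responses of the PEON set in their O_P-standard conditions,
    with sequence positions, on the given split."""
    omissions = _omission_trials(rec)
    trials = split_events(omissions, split)
    prob = {
        t: rec.conditions.set_index("condition_id")["prob_a" if t == "A" else "prob_b"]
        for t in "AB"
    }
    resp_all, pos_all = [], []
    for _, row in peons.iterrows():
        st = rec.spike_train(row["neuron_id"])
        probs_op = prob[row["o_p_tone"]].loc[trials["condition_id"]].to_numpy()
        standard = probs_op >= STANDARD_PROB_MIN - 1e-9
        resp_all.append(event_responses(st, trials["onset_ms"].to_numpy()[standard]))
        pos_all.append(trials["item_index"].to_numpy()[standard])
    return np.concatenate(resp_all), np.concatenate(pos_all)


def _pooled_adaptation_inputs(rec, peons, max_trials=50):
    """O_P-tone responses over the first presentations in the conditions where
    that tone is the standard (the non-specific-drift control).

    Presentation order must be preserved, so no subsampling or splitting is
    applied here: the adaptation transient lives entirely in the first few
    presentations.
    """
    prob = {
        t: rec.conditions.set_index("condition_id")["prob_a" if t == "A" else "prob_b"]
        for t in "AB"
    }
    resp_all, num_all = [], []
    for _, row in peons.iterrows():
        st = rec.spike_train(row["neuron_id"])
        tone = row["o_p_tone"]
        ev = rec.events[rec.events["label"] == tone].sort_values(
            ["condition_id", "onset_ms"]
        )
        pres = ev.groupby("condition_id").cumcount().to_numpy() + 1
        probs_op = prob[tone].loc[ev["condition_id"]].to_numpy()
        keep = (pres <= max_trials) & (probs_op >= STANDARD_PROB_MIN - 1e-9)
        resp_all.append(event_responses(st, ev["onset_ms"].to_numpy()[keep]))
        num_all.append(pres[keep])
    return np.concatenate(resp_all), np.concatenate(num_all)


def reproduce_ephys_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    generator: Optional[GeneratorConfig] = None,
    alpha: float = 0.05,
    n_boot: int = 300_000,
) -> dict:
    """Synthetic recording -> classification -> fits -> selectivity -> bootstrap.

    Returns the per-split classification tables, the ODD/EVEN overlap
    statistics, pooled fits, selectivity labels, laminar/areal bootstraps and
    a recovery report against the planted ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if generator is None:
        generator = GeneratorConfig(seed=child_seed(seed, 10))
    log.info("generating synthetic recording (%d neurons)", generator.n_neurons)
    rec, truth = generate_recording(generator)
    rec.validate()

    tables = {}
    for split in ("ODD", "EVEN", "ALL"):
        log.info("classifying split=%s", split)
        tables[split] = classify_peons(rec, split=split, alpha=alpha)
    classification = pd.concat(tables.values(), ignore_index=True)
    classification.to_csv(out / "classification.csv", index=False)

    peon_ids = {
        s: set(t.loc[t["category"] == "peon", "neuron_id"]) for s, t in tables.items()
    }
    overlap = overlap_statistics(
        len(peon_ids["ODD"]),
        len(peon_ids["EVEN"]),
        generator.n_neurons,
        len(peon_ids["ODD"] & peon_ids["EVEN"]),
    )

    peons_odd = tables["ODD"][tables["ODD"]["category"] == "peon"]
    fits = {}
    if len(peons_odd) > 0:
        resp, pos = _pooled_buildup_inputs(rec, peons_odd, "EVEN")
        fits["buildup"] = buildup_fit(resp, pos)
        resp, num = _pooled_adaptation_inputs(rec, peons_odd)
        fits["adaptation"] = adaptation_fit(resp, num)
        fit_payload = {
            name: dict(model=f.model, params=list(f.params),
                       r_squared=f.r_squared, converged=f.converged)
            for name, f in fits.items()
        }
        (out / "fits.json").write_text(json.dumps(fit_payload, indent=1))

    selectivity = pd.DataFrame(
        [
            selectivity_classification(
                rec, row["neuron_id"], row["o_p_tone"], split="EVEN", alpha=alpha
            )
            for _, row in peons_odd.iterrows()
        ]
    )
    if len(selectivity):
        selectivity.to_csv(out / "selectivity.csv", index=False)

    is_peon = rec.neurons["neuron_id"].isin(peon_ids["ODD"]).to_numpy()
    boots = {}
    for group_col in ("layer", "field"):
        boots[group_col] = group_bootstrap(
            is_peon,
            rec.neurons[group_col].to_numpy(),
            n_boot=n_boot,
            seed=child_seed(seed, 11),
        )
        boots[group_col].to_csv(out / f"bootstrap_{group_col}.csv", index=False)

    pop_corr = population_tone_correlations(rec, peons_odd, split="EVEN")
    pop_corr.to_csv(out / "population_correlations.csv", index=False)

    # recovery vs planted truth (ODD training split)
    tr = truth.frame
    merged = tables["ODD"].merge(tr, on="neuron_id", suffixes=("", "_true"))
    planted = merged["is_peon"]
    called = merged["category"] == "peon"
    sensitivity = float((called & planted).sum() / max(planted.sum(), 1))
    false_pos = float((called & ~planted).sum() / max((~planted).sum(), 1))
    op_match = merged.loc[called & planted, "o_p_tone"] == merged.loc[
        called & planted, "o_p_tone_true"
    ]
    recovery = {
        "n_neurons": int(generator.n_neurons),
        "n_planted": int(planted.sum()),
        "n_called_odd": int(called.sum()),
        "n_called_even": len(peon_ids["EVEN"]),
        "sensitivity": sensitivity,
        "false_positive_rate": false_pos,
        "o_p_accuracy": float(op_match.mean()) if len(op_match) else np.nan,
        "overlap_observed": len(peon_ids["ODD"] & peon_ids["EVEN"]),
        "overlap_expected": overlap.expected,
        "overlap_p": overlap.p_value,
    }
    (out / "recovery.json").write_text(json.dumps(recovery, indent=1, default=float))
    write_manifest(
        out,
        {"stage": "ephys_pipeline", "generator": asdict(generator),
         "alpha": alpha, "n_boot": n_boot},
        seed,
    )
    return {
        "recording": rec,
        "truth": truth,
        "classification": tables,
        "overlap": overlap,
        "fits": fits,
        "selectivity": selectivity,
        "bootstraps": boots,
        "population_correlations": pop_corr,
        "recovery": recovery,
    }
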