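#!/usr/bin/env python
"""Probability-encoding comparison of the three connectivity variants.

Sweeps Prob(A) from 0 to 0.95 in 0.05 steps (500 stimuli per condition,
5 % omissions) for the lateral PE+ -> PE-, lateral I -> PE- and no-lateral
circuits, then correlates the stream-2 PEON's per-trial spike counts with
Prob(A) separately for omission, Tone-A and Tone-B trials.  Only the
PE+ -> PE- model reproduces the experimentally observed sign pattern
(omission +, Tone A -, Tone B +).

Writes results/02_variant_sweeps/{sweep_correlations,sign_report}.csv.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from peons.circuit import CircuitConfig
from peons.model_eval import (
    correlation_sign_report,
    probability_sweep,
    sweep_correlations,
)
from peons.stimuli import child_seed

OUT = Path(__file__).resolve().parents[1] / "results" / "02_variant_sweeps"


def main(seed: int) -> None:
    frames = []
    for variant in ("lateral_pe_to_pe", "lateral_i_to_pe", "none"):
        cfg = replace(CircuitConfig(), variant=variant)
        sweep = probability_sweep(cfg, seed=child_seed(seed, 1))
        frames.append(sweep_correlations(sweep))
    corr = pd.concat(frames, ignore_index=True)
    signs = correlation_sign_report(corr)

    OUT.mkdir(parents=True, exist_ok=True)
    corr.to_csv(OUT / "sweep_correlations.csv", index=False)
    signs.to_csv(OUT / "sign_report.csv", index=False)

    print("Trial-level Spearman correlations with Prob(A):")
    print(corr[["variant", "label", "rho", "p", "n", "flagged"]].to_string(index=False))
    print("\nSign pattern vs the experimental one (O:+, A:-, B:+):")
    print(signs.to_string(index=False))
    matching = signs.loc[signs["matches_experiment"], "variant"].tolist()
    print(f"\nFinding: variant(s) matching the experimental pattern: {matching}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
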