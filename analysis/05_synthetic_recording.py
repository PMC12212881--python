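#!/usr/bin/env python
"""Generate the synthetic reference recording used by the analysis pipeline.

Draws a 200-neuron recording over the eight oddball-with-omission conditions
with 15 % planted PEONs (logistic omission buildup, probability-scaled
amplitudes, adapting tone responses) and writes the CSV schema plus the
ground-truth sidecar.  The full recording tables are large, so they go under
scratch/; the per-neuron ground-truth summary goes under results/.
"""

import argparse
from pathlib import Path

from peons.synthdata import GeneratorConfig, generate_recording

ROOT = Path(__file__).resolve().parents[1]
OUT_DATA = ROOT / "scratch" / "synthetic_recording"
OUT_RES = ROOT / "results" / "05_synthetic_recording"


def main(seed: int, n_neurons: int) -> None:
    cfg = GeneratorConfig(n_neurons=n_neurons, seed=seed)
    rec, truth = generate_recording(cfg)
    rec.validate()
    rec.to_csv(OUT_DATA)
    truth.to_json(OUT_DATA / "ground_truth.json")
    OUT_RES.mkdir(parents=True, exist_ok=True)
    truth.frame.to_csv(OUT_RES / "ground_truth_summary.csv", index=False)

    n_peons = int(truth.frame["is_peon"].sum())
    print(f"Wrote {len(rec.spikes):,} spikes from {n_neurons} neurons to {OUT_DATA}")
    print(f"Planted PEONs: {n_peons} ({n_peons / n_neurons:.0%})")
    print(truth.frame["selectivity"].value_counts().to_string())


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-neurons", type=int, default=200)
    args = ap.parse_args()
    main(args.seed, args.n_neurons)
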