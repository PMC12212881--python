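"""Oddball-with-omission stimulus sequences.

A condition fixes the probabilities of Tone A, Tone B and omissions (O) in a
sequence of regularly spaced items (one item every ``soa`` ms).  Sequences are
*count-exact*: a 1,000-item condition at 5 % omissions contains exactly 50
omission events, which the split-half classification downstream relies on
(25 training / 25 testing omissions per condition).  All randomness is the
order of the items, drawn as a seeded uniform permutation of the fixed label
multiset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LABELS = ("A", "B", "O")

#: Prob(A) of the eight experimental conditions (Prob(B) = 0.95 - Prob(A),
#: omissions fixed at 5 %).
EXPERIMENT_PROB_A = (0.95, 0.90, 0.85, 0.75, 0.50, 0.20, 0.10, 0.0)

DEFAULT_SOA_MS = 150.0
OMISSION_RATE = 0.05


class CompositionError(ValueError):
    """Probabilities do not yield integer label counts for ``n_items``."""


@dataclass(frozen=True)
class Condition:
    """One stimulus condition: label probabilities, length, timing and seed."""

    prob_a: float
    prob_b: float
    prob_omission: float = OMISSION_RATE
    n_items: int = 1000
    soa: float = DEFAULT_SOA_MS
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.prob_a + self.prob_b + self.prob_omission
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"label probabilities sum to {total!r}, not 1")
        if min(self.prob_a, self.prob_b, self.prob_omission) < 0:
            raise ValueError("probabilities must be non-negative")
        if self.n_items <= 0:
            raise ValueError("n_items must be positive")
        if self.soa <= 0:
            raise ValueError("soa must be positive")

    @property
    def counts(self) -> dict[str, int]:
        """Exact per-label counts; raises if any expected count is non-integer."""
        out = {}
        for label, p in zip(LABELS, (self.prob_a, self.prob_b, self.prob_omission)):
            expected = p * self.n_items
            rounded = round(expected)
            if abs(expected - rounded) > 1e-9:
                raise CompositionError(
                    f"prob({label}) * n_items = {expected} is not an integer"
                )
            out[label] = int(rounded)
        return out

    @property
    def duration_ms(self) -> float:
        return self.n_items * self.soa


@dataclass(frozen=True)
class ToneSequence:
    """An ordered realization of a condition: labels and onset times (ms)."""

    items: np.ndarray          # dtype '<U1', values in {A, B, O}
    onsets: np.ndarray         # ms, onsets[k] = k * soa
    condition: Condition

    def __len__(self) -> int:
        return len(self.items)

    def positions(self, label: str) -> np.ndarray:
        """0-based sequence positions of the given label."""
        return np.flatnonzero(self.items == label)

    def to_frame(self, condition_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_index": np.arange(len(self.items)),
                "label": self.items,
                "onset_ms": self.onsets,
                "condition_id": condition_id,
            }
        )


def generate_sequence(condition: Condition) -> ToneSequence:
    """Seeded uniform random permutation of the condition's exact label multiset."""
    counts = condition.counts
    labels = np.repeat(
        np.array(LABELS, dtype="<U1"), [counts[lab] for lab in LABELS]
    )
    rng = np.random.default_rng(condition.seed)
    rng.shuffle(labels)
    onsets = np.arange(condition.n_items, dtype=float) * condition.soa
    return ToneSequence(items=labels, onsets=onsets, condition=condition)


def event_onsets(seq: ToneSequence) -> np.ndarray:
    """Onset time of every item: ``onsets[k] = k * soa`` (ms)."""
    return seq.onsets


def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic sub-seed derivation, kept below 2**31."""
    ss = np.random.SeedSequence([int(root_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def experiment_conditions(
    n_items: int = 1000,
    soa: float = DEFAULT_SOA_MS,
    seed: int = 0,
    prob_a_values: Sequence[float] = EXPERIMENT_PROB_A,
) -> list[Condition]:
    """The eight oddball conditions (Prob(A) from 95 % down to 0 %)."""
    return [
        Condition(
            prob_a=pa,
            prob_b=round(1.0 - OMISSION_RATE - pa, 10),
            prob_omission=OMISSION_RATE,
            n_items=n_items,
            soa=soa,
            seed=child_seed(seed, i),
        )
        for i, pa in enumerate(prob_a_values)
    ]


def model_grid(step: float = 0.05, max_prob_a: float = 0.95) -> np.ndarray:
    """Prob(A) grid for model sweeps: 0 to ``max_prob_a`` inclusive."""
    n = int(round(max_prob_a / step))
    grid = np.round(np.arange(n + 1) * step, 10)
    return grid


def sequences_frame(seqs: Sequence[ToneSequence]) -> pd.DataFrame:
    """Event-table CSV layout: item_index, label, onset_ms, condition_id."""
    return pd.concat(
        [s.to_frame(condition_id=i) for i, s in enumerate(seqs)], ignore_index=True
    )
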