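"""Omission-response analysis pipeline for multi-neuron spike recordings.

Implements the statistics used to find Probability Encoding Omission Neurons
(PEONs) in oddball-with-omission recordings:

* baseline-corrected omission/tone response rates (response window 5-120 ms
  after the expected onset, local baseline -24 to +5 ms);
* trial-level Spearman correlation of omission responses with the preferred
  tone's probability, and k-means clustering of the per-neuron coefficients;
* split-half (odd/even trial) PEON classification with a Wilcoxon sign-rank
  criterion on the conditions where the preferred tone is the standard;
* logistic buildup fits over sequence position and exponential
  adaptation fits over early tone trials;
* tone/omission selectivity indices and categories;
* hypergeometric overlap statistics and permutation bootstraps for laminar
  and areal enrichment.

All time windows are half-open ``[start, end)`` in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

RESPONSE_WINDOW_MS = (5.0, 120.0)
BASELINE_WINDOW_MS = (-24.0, 5.0)
STANDARD_PROB_MIN = 0.75         # conditions where a tone counts as "standard"
LAYER_BOUNDS_UM = ((0.0, 600.0), (600.0, 900.0), (900.0, 1400.0))
LAYER_NAMES = ("supragranular", "granular", "infragranular")


def layer_from_depth(depth_um: float) -> str:
    """Cortical depth band: 0-600 supragranular, 600-900 granular,
    900-1400 infragranular (um below the pial surface)."""
    for (lo, hi), name in zip(LAYER_BOUNDS_UM, LAYER_NAMES):
        if lo <= depth_um < hi:
            return name
    return LAYER_NAMES[-1] if depth_um >= LAYER_BOUNDS_UM[-1][0] else LAYER_NAMES[0]


@dataclass
class SpikeRecording:
    """Spike trains, the event/condition tables, and per-neuron metadata.

    ``spikes``: neuron_id, spike_time_ms (global times).
    ``events``: condition_id, item_index, label (A|B|O), onset_ms (global).
    ``neurons``: neuron_id, depth_um, layer, field.
    ``conditions``: condition_id, prob_a, prob_b.
    """

    spikes: pd.DataFrame
    events: pd.DataFrame
    neurons: pd.DataFrame
    conditions: pd.DataFrame

    def __post_init__(self) -> None:
        self._trains: Optional[dict[int, np.ndarray]] = None

    def validate(self) -> None:
        known = set(self.neurons["neuron_id"])
        if not set(self.spikes["neuron_id"]).issubset(known):
            raise ValueError("spike table references unknown neuron_id")
        for cid, ev in self.events.groupby("condition_id"):
            onsets = ev["onset_ms"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise ValueError(f"onsets not strictly increasing in condition {cid}")
            cond = self.conditions[self.conditions["condition_id"] == cid].iloc[0]
            n = len(ev)
            n_omissions = int((ev["label"] == "O").sum())
            expected = round((1.0 - cond["prob_a"] - cond["prob_b"]) * n)
            if n_omissions != expected:
                raise ValueError(
                    f"condition {cid}: {n_omissions} omissions, expected {expected}"
                )

    def spike_train(self, neuron_id: int) -> np.ndarray:
        """Sorted spike times of one neuron (cached)."""
        if self._trains is None:
            order = self.spikes.sort_values(["neuron_id", "spike_time_ms"])
            self._trains = {
                int(nid): g["spike_time_ms"].to_numpy(dtype=float)
                for nid, g in order.groupby("neuron_id")
            }
        return self._trains.get(int(neuron_id), np.empty(0))

    def prob_of_tone(self, condition_id: int, tone: str) -> float:
        row = self.conditions[self.conditions["condition_id"] == condition_id].iloc[0]
        return float(row["prob_a"] if tone == "A" else row["prob_b"])

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / "spikes.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.neurons.to_csv(out / "neurons.csv", index=False)
        self.conditions.to_csv(out / "conditions.csv", index=False)

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "SpikeRecording":
        p = Path(in_dir)
        return cls(
            spikes=pd.read_csv(p / "spikes.csv"),
            events=pd.read_csv(p / "events.csv"),
            neurons=pd.read_csv(p / "neurons.csv"),
            conditions=pd.read_csv(p / "conditions.csv"),
        )


def event_responses(spike_times: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Baseline-corrected rate (spikes/s) for each event onset.

    Response = rate in [onset+5, onset+120) minus rate in [onset-24, onset+5).
    """
    st = np.asarray(spike_times, dtype=float)
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    r0, r1 = RESPONSE_WINDOW_MS
    b0, b1 = BASELINE_WINDOW_MS
    resp = (
        np.searchsorted(st, onsets + r1) - np.searchsorted(st, onsets + r0)
    ) / ((r1 - r0) / 1000.0)
    base = (
        np.searchsorted(st, onsets + b1) - np.searchsorted(st, onsets + b0)
    ) / ((b1 - b0) / 1000.0)
    return resp - base


def omission_response(spike_times: np.ndarray, expected_onset: float) -> float:
    """Baseline-corrected firing rate around one expected-but-omitted tone."""
    return float(event_responses(spike_times, [expected_onset])[0])


def tone_response(spike_times: np.ndarray, onset: float) -> float:
    """Same two-window statistic applied at a tone onset (for comparability)."""
    return float(event_responses(spike_times, [onset])[0])


def split_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trials (ordered by occurrence) into the odd-indexed (1st, 3rd, ...)
    training half and the even-indexed testing half."""
    trials = trials.reset_index(drop=True)
    return trials.iloc[0::2], trials.iloc[1::2]


def select_split(trials: pd.DataFrame, split: str) -> pd.DataFrame:
    """Trials belonging to a named split: ODD (1st, 3rd, ...), EVEN, or ALL."""
    if split == "ALL":
        return trials.reset_index(drop=True)
    odd, even = split_trials(trials)
    if split == "ODD":
        return odd
    if split == "EVEN":
        return even
    raise ValueError(f"unknown split {split!r}")


def subsample_trials(trials: pd.DataFrame, target: int = 50) -> pd.DataFrame:
    """Every-k-th subsampling down to ``target`` trials (k = floor(n/target))."""
    trials = trials.reset_index(drop=True)
    n = len(trials)
    if n <= target:
        return trials
    k = n // target
    return trials.iloc[::k].iloc[:target]


def _wilcoxon_greater(values: np.ndarray, alpha_nan: float = 1.0) -> float:
    """One-sample Wilcoxon sign-rank p-value for median > 0 (zeros discarded)."""
    values = np.asarray(values, dtype=float)
    values = values[values != 0.0]
    if len(values) == 0:
        return alpha_nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return float(stats.wilcoxon(values, alternative="greater").pvalue)
        except ValueError:
            return alpha_nan


def probability_correlation(
    responses: np.ndarray, probs_a: np.ndarray
) -> tuple[float, float, str, bool]:
    """Trial-level Spearman correlation against the preferred tone's probability.

    Returns (rho, p, o_p_tone, flagged): the preferred (O_P) tone is the one
    whose probability correlates positively; since Prob(B) decreases exactly
    as Prob(A) increases, the rank correlation against Prob(B) is the
    negation of the one against Prob(A).
    """
    responses = np.asarray(responses, dtype=float)
    probs_a = np.asarray(probs_a, dtype=float)
    if len(responses) < 3 or np.ptp(responses) == 0 or np.ptp(probs_a) == 0:
        return 0.0, 1.0, "A", True
    rho_a, p = stats.spearmanr(responses, probs_a)
    if np.isnan(rho_a):
        return 0.0, 1.0, "A", True
    if rho_a >= 0:
        return float(rho_a), float(p), "A", False
    return float(-rho_a), float(p), "B", False


def _omission_trials(rec: SpikeRecording) -> pd.DataFrame:
    ev = rec.events[rec.events["label"] == "O"]
    return ev.sort_values(["condition_id", "onset_ms"])


def split_events(events: pd.DataFrame, split: str) -> pd.DataFrame:
    """Per-condition odd/even-position split of an event table (vectorized
    equivalent of ``select_split`` applied within each condition)."""
    if split == "ALL":
        return events.reset_index(drop=True)
    if split not in ("ODD", "EVEN"):
        raise ValueError(f"unknown split {split!r}")
    pos = events.groupby("condition_id").cumcount()
    keep = pos % 2 == (0 if split == "ODD" else 1)
    return events[keep].reset_index(drop=True)


def classify_peons(
    rec: SpikeRecording, split: str = "ODD", alpha: float = 0.05
) -> pd.DataFrame:
    """Per-neuron PEON classification on a training split.

    Criterion 1: significant trial-level Spearman correlation between the
    training-split omission responses and the O_P tone's probability.
    Criterion 2: significant positive omission response (one-sample Wilcoxon
    sign-rank, median > 0) pooled over the conditions where the O_P tone is
    the standard (probability >= 0.75).  Category is ``peon`` when both pass,
    ``correlation_only`` when only the first does, otherwise ``none``.
    """
    omissions = _omission_trials(rec)
    train = split_events(omissions, split)
    prob_a = rec.conditions.set_index("condition_id")["prob_a"]
    prob_b = rec.conditions.set_index("condition_id")["prob_b"]
    rows = []
    for nid in rec.neurons["neuron_id"]:
        st = rec.spike_train(nid)
        if len(train) == 0:
            rows.append(dict(neuron_id=nid, split=split, rho_train=np.nan,
                             p_train=np.nan, o_p_tone="A", wilcoxon_p_train=np.nan,
                             category="none", flagged=True))
            continue
        resp = event_responses(st, train["onset_ms"].to_numpy())
        pa = prob_a.loc[train["condition_id"]].to_numpy()
        rho, p, o_p, flagged = probability_correlation(resp, pa)
        probs_op = (prob_a if o_p == "A" else prob_b).loc[
            train["condition_id"]
        ].to_numpy()
        standard = probs_op >= STANDARD_PROB_MIN - 1e-9
        wilc_p = _wilcoxon_greater(resp[standard]) if standard.any() else 1.0
        corr_ok = (not flagged) and p < alpha
        if corr_ok and wilc_p < alpha:
            category = "peon"
        elif corr_ok:
            category = "correlation_only"
        else:
            category = "none"
        rows.append(
            dict(neuron_id=nid, split=split, rho_train=rho, p_train=p,
                 o_p_tone=o_p, wilcoxon_p_train=wilc_p, category=category,
                 flagged=flagged)
        )
    return pd.DataFrame(rows)


def cluster_correlation_coeffs(
    rhos: np.ndarray, k_max: int = 10, replicates: int = 10, seed: int = 0
) -> tuple[int, np.ndarray, np.ndarray]:
    """k-means over per-neuron correlation coefficients with a WCSS knee.

    Returns (k_opt, assignments at k_opt, wcss for k = 1..k_max).  The knee is
    the k with maximum perpendicular distance to the chord from (1, wcss_1)
    to (k_max, wcss_kmax) after normalizing both axes to [0, 1].
    """
    rhos = np.asarray(rhos, dtype=float).reshape(-1, 1)
    if len(rhos) < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} values")
    if np.ptp(rhos) == 0:
        return 1, np.zeros(len(rhos), dtype=int), np.zeros(k_max)
    wcss = np.empty(k_max)
    labels = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
        labels[k] = km.fit_predict(rhos)
        wcss[k - 1] = km.inertia_
    ks = np.arange(1, k_max + 1, dtype=float)
    x = (ks - 1) / (k_max - 1)
    denom = wcss[0] - wcss[-1]
    if denom <= 0:
        return 1, labels[1], wcss
    y = (wcss - wcss[-1]) / denom
    # distance from each point to the chord y = 1 - x
    dist = np.abs(y + x - 1.0) / np.sqrt(2.0)
    k_opt = int(np.argmax(dist)) + 1
    return k_opt, labels[k_opt], wcss


@dataclass
class OverlapResult:
    expected: float
    p_value: Optional[float]


def overlap_statistics(
    n_first: int, n_second: int, n_total: int, n_overlap: Optional[int] = None
) -> OverlapResult:
    """Chance-level expectation and upper-tail hypergeometric p for the overlap
    of two independently classified neuron subsets."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_first > n_total or n_second > n_total:
        raise ValueError("subset larger than population")
    expected = n_first * n_second / n_total
    p = None
    if n_overlap is not None:
        p = float(stats.hypergeom.sf(n_overlap - 1, n_total, n_first, n_second))
    return OverlapResult(expected=expected, p_value=p)


@dataclass
class FitResult:
    model: str
    params: tuple
    r_squared: float
    binned: pd.DataFrame
    converged: bool


def _logistic(n, a, b, c):
    return a / (1.0 + np.exp(-b * (n - c)))


def _exponential(n, d, e, f):
    return d + e * np.exp(-np.clip(f * n, -500, 500))


def buildup_fit(
    responses: np.ndarray,
    positions: np.ndarray,
    bin_width: int = 50,
    min_bins: int = 6,
) -> FitResult:
    """Logistic growth fit of omission responses over sequence position.

    Responses are binned by position (default width 50 items), and
    ``FR(n) = a / (1 + exp(-b (n - c)))`` is fitted to the bin means by
    nonlinear least squares.
    """
    responses = np.asarray(responses, dtype=float)
    positions = np.asarray(positions, dtype=float)
    bins = (positions // bin_width).astype(int)
    grp = pd.DataFrame({"bin": bins, "resp": responses}).groupby("bin")["resp"]
    binned = pd.DataFrame(
        {
            "center": (grp.mean().index + 0.5) * bin_width,
            "mean": grp.mean().to_numpy(),
            "sem": grp.sem().to_numpy(),
            "n": grp.size().to_numpy(),
        }
    ).reset_index(drop=True)
    if len(binned) < min_bins:
        raise ValueError(f"need data in at least {min_bins} bins, got {len(binned)}")
    x = binned["center"].to_numpy()
    y = binned["mean"].to_numpy()
    p0 = (max(y.max(), 1e-6), 0.01, float(np.median(x)))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.full(3, np.nan), False
    if converged:
        resid = y - _logistic(x, *popt)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else np.nan
    else:
        r2 = np.nan
    return FitResult("logistic", tuple(popt), float(r2), binned, converged)


def adaptation_fit(
    responses: np.ndarray, trial_numbers: np.ndarray, max_trials: int = 50
) -> FitResult:
    """Exponential decay fit ``FR(n) = d + e exp(-f n)`` of tone responses
    over the first trials (stimulus-specific adaptation control)."""
    responses = np.asarray(responses, dtype=float)
    trial_numbers = np.asarray(trial_numbers, dtype=float)
    keep = trial_numbers <= max_trials
    grp = pd.DataFrame(
        {"n": trial_numbers[keep], "resp": responses[keep]}
    ).groupby("n")["resp"]
    binned = pd.DataFrame(
        {
            "center": grp.mean().index.to_numpy(),
            "mean": grp.mean().to_numpy(),
            "sem": grp.sem().to_numpy(),
            "n": grp.size().to_numpy(),
        }
    )
    if len(binned) < 4:
        raise ValueError("need at least 4 distinct trial numbers")
    x = binned["center"].to_numpy()
    y = binned["mean"].to_numpy()
    tail = y[len(y) // 2:].mean()
    transient = max(y[0] - tail, 1e-6)
    best, best_sse = None, np.inf
    for f0 in (0.1, 1.0, 3.0):
        p0 = (tail, transient * np.exp(f0 * x[0]), f0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(_exponential, x, y, p0=p0, maxfev=20000)
            sse = ((y - _exponential(x, *popt)) ** 2).sum()
            if sse < best_sse:
                best, best_sse = popt, sse
        except RuntimeError:
            continue
    converged = best is not None
    if converged:
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else np.nan
        popt = best
    else:
        popt, r2 = np.full(3, np.nan), np.nan
    return FitResult("exponential", tuple(popt), float(r2), binned, converged)


def selectivity_indices(
    t_op: float, t_onp: float, o_op: float, o_onp: float
) -> tuple[Optional[float], Optional[float]]:
    """Tone and omission selectivity indices, ``(x - y) / (x + y)``; None when
    the denominator vanishes."""
    tsi = (t_op - t_onp) / (t_op + t_onp) if (t_op + t_onp) != 0 else None
    osi = (o_op - o_onp) / (o_op + o_onp) if (o_op + o_onp) != 0 else None
    return tsi, osi


def _tone_trials_split(
    rec: SpikeRecording, tone: str, split: str, target: int = 50
) -> pd.DataFrame:
    """Subsampled (50/condition), split-matched tone trials for one tone."""
    ev = rec.events[rec.events["label"] == tone].sort_values(
        ["condition_id", "onset_ms"]
    )
    parts = []
    for cid, g in ev.groupby("condition_id"):
        parts.append(select_split(subsample_trials(g, target), split))
    if not parts:
        return ev.iloc[:0]
    return pd.concat(parts, ignore_index=True)


def selectivity_classification(
    rec: SpikeRecording,
    neuron_id: int,
    o_p_tone: str,
    split: str = "EVEN",
    alpha: float = 0.05,
) -> dict:
    """Testing-split omission- and tone-selectivity labels for one neuron.

    Omission label: ``selective`` if the Wilcoxon omission criterion passes in
    the O_P-standard conditions but not in the O_NP-standard conditions,
    ``non_selective`` if it passes in both, ``none`` otherwise.  Tone label:
    ``both`` / ``OP_only`` / ``ONP_only`` / ``neither`` from Wilcoxon tests of
    the subsampled, split-matched tone responses against zero.
    """
    o_np_tone = "B" if o_p_tone == "A" else "A"
    st = rec.spike_train(neuron_id)
    omissions = _omission_trials(rec)
    test = split_events(omissions, split)
    prob = {
        t: rec.conditions.set_index("condition_id")[
            "prob_a" if t == "A" else "prob_b"
        ]
        for t in "AB"
    }
    out = {"neuron_id": neuron_id, "o_p_tone": o_p_tone, "split": split}
    ps = {}
    for tone_key, tone in (("op", o_p_tone), ("onp", o_np_tone)):
        probs = prob[tone].loc[test["condition_id"]].to_numpy()
        standard = probs >= STANDARD_PROB_MIN - 1e-9
        if not standard.any():
            ps[tone_key] = None
            continue
        resp = event_responses(st, test["onset_ms"].to_numpy()[standard])
        ps[tone_key] = _wilcoxon_greater(resp)
    if ps["op"] is None or ps["onp"] is None:
        out["omission_label"] = "unlabeled"
    elif ps["op"] < alpha and ps["onp"] >= alpha:
        out["omission_label"] = "selective"
    elif ps["op"] < alpha and ps["onp"] < alpha:
        out["omission_label"] = "non_selective"
    else:
        out["omission_label"] = "none"
    out["omission_p_op"], out["omission_p_onp"] = ps["op"], ps["onp"]

    tone_sig = {}
    for tone_key, tone in (("op", o_p_tone), ("onp", o_np_tone)):
        trials = _tone_trials_split(rec, tone, split)
        if len(trials) == 0:
            tone_sig[tone_key] = False
            continue
        resp = event_responses(st, trials["onset_ms"].to_numpy())
        tone_sig[tone_key] = _wilcoxon_greater(resp) < alpha
    out["tone_label"] = {
        (True, True): "both",
        (True, False): "OP_only",
        (False, True): "ONP_only",
        (False, False): "neither",
    }[(tone_sig["op"], tone_sig["onp"])]

    # selectivity indices from mean rates (conditions where each tone occurs /
    # is the standard)
    rates = {}
    for tone_key, tone in (("op", o_p_tone), ("onp", o_np_tone)):
        trials = _tone_trials_split(rec, tone, split)
        rates[f"t_{tone_key}"] = (
            float(event_responses(st, trials["onset_ms"].to_numpy()).mean())
            if len(trials)
            else 0.0
        )
        probs = prob[tone].loc[test["condition_id"]].to_numpy()
        standard = probs >= STANDARD_PROB_MIN - 1e-9
        rates[f"o_{tone_key}"] = (
            float(
                event_responses(
                    st, test["onset_ms"].to_numpy()[standard]
                ).mean()
            )
            if standard.any()
            else 0.0
        )
    tsi, osi = selectivity_indices(
        rates["t_op"], rates["t_onp"], rates["o_op"], rates["o_onp"]
    )
    out["tsi"], out["osi"] = tsi, osi
    return out


def group_bootstrap(
    is_peon: np.ndarray,
    groups: np.ndarray,
    n_boot: int = 300_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation (without replacement) null for per-group PEON counts.

    Each iteration redraws ``n_peon`` neurons uniformly without replacement and
    counts how many fall in each group (a multivariate hypergeometric draw).
    The two-sided p is the fraction of null counts at least as far from the
    null mean as the observed count, floored at ``1 / n_boot``.
    """
    is_peon = np.asarray(is_peon, dtype=bool)
    groups = np.asarray(groups)
    if len(is_peon) != len(groups):
        raise ValueError("is_peon and groups must align")
    names, inverse = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(names))
    observed = np.bincount(inverse[is_peon], minlength=len(names))
    n_peon = int(is_peon.sum())
    rng = np.random.default_rng(seed)
    null = rng.multivariate_hypergeometric(sizes, n_peon, size=n_boot)
    rows = []
    for gi, name in enumerate(names):
        if sizes[gi] == 0:
            rows.append(dict(group=name, n_group=0, observed=0, null_mean=np.nan,
                             p=np.nan, flagged=True))
            continue
        mean = null[:, gi].mean()
        extreme = np.abs(null[:, gi] - mean) >= abs(observed[gi] - mean)
        p = max(float(extreme.mean()), 1.0 / n_boot)
        rows.append(dict(group=name, n_group=int(sizes[gi]),
                         observed=int(observed[gi]), null_mean=float(mean),
                         p=p, flagged=False))
    return pd.DataFrame(rows)


def population_tone_correlations(
    rec: SpikeRecording,
    peons: pd.DataFrame,
    split: str = "EVEN",
) -> pd.DataFrame:
    """Pooled trial-level correlations of PEON responses with Prob(O_P).

    ``peons`` must carry ``neuron_id`` and ``o_p_tone``.  Three response
    types: omission responses over all conditions, and subsampled
    split-matched tone responses over the conditions where each tone occurs.
    """
    omissions = _omission_trials(rec)
    test = split_events(omissions, split)
    prob = {
        t: rec.conditions.set_index("condition_id")[
            "prob_a" if t == "A" else "prob_b"
        ]
        for t in "AB"
    }
    pooled: dict[str, tuple[list, list]] = {
        "omission": ([], []),
        "tone_op": ([], []),
        "tone_onp": ([], []),
    }
    for _, row in peons.iterrows():
        nid, o_p = row["neuron_id"], row["o_p_tone"]
        o_np = "B" if o_p == "A" else "A"
        st = rec.spike_train(nid)
        x = prob[o_p].loc[test["condition_id"]].to_numpy()
        y = event_responses(st, test["onset_ms"].to_numpy())
        pooled["omission"][0].extend(y)
        pooled["omission"][1].extend(x)
        for key, tone in (("tone_op", o_p), ("tone_onp", o_np)):
            trials = _tone_trials_split(rec, tone, split)
            if len(trials) == 0:
                continue
            y = event_responses(st, trials["onset_ms"].to_numpy())
            x = prob[o_p].loc[trials["condition_id"]].to_numpy()
            pooled[key][0].extend(y)
            pooled[key][1].extend(x)
    rows = []
    for key, (y, x) in pooled.items():
        y, x = np.asarray(y), np.asarray(x)
        if len(y) < 3 or np.ptp(y) == 0 or np.ptp(x) == 0:
            rows.append(dict(response_type=key, rho=0.0, p=1.0, n=len(y),
                             flagged=True))
            continue
        rho, p = stats.spearmanr(y, x)
        rows.append(dict(response_type=key, rho=float(rho), p=float(p),
                         n=len(y), flagged=False))
    return pd.DataFrame(rows)
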