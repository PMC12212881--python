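# Methods

## The circuit model

Each of the five streams is a predictive-coding module of six
leaky integrate-and-fire neurons (I, P, PE+, PE−, I+, I−) obeying
`tau_m dV/dt = -V + R_m (I_exc - I_inh + I_pred + I_stim)` with
`tau_m = 30 ms`, `R_m = 1 MΩ`, threshold 10 mV, reset 0 mV and a 2-ms
refractory clamp.  Units are chosen so that a 0.2 µA input drives the
membrane toward 200 mV.  Synaptic currents rise instantaneously by the
synaptic weight on each delivered (delayed) spike and decay exponentially
with `tau_exc = 5 ms` / `tau_inh = 20 ms`.

Stimuli are 20-ms current pulses at 150-ms onset asynchrony: tone trials
drive the I neuron at `0.2 µA` (full-strength stream) or `0.1 µA`
(neighbouring streams); every trial drives the P neuron at
`P_strength × 0.2 µA`, encoding the assumption that the prediction's
*timing* is learned elsewhere while the circuit adjusts only its *gain*.
`P_strength` is updated per spike (+0.001 per PE+, −0.0003 per PE−, clipped
to [0, 1]).  Treating the spike indicator as a Dirac impulse — rather than a
rate multiplied by the integration step — is deliberate: with rate-times-dt
semantics the prediction gain could not plateau within a 75-s sequence.

Lateral connectivity follows the distance laws `w = 1.2/(Δ stream)² µA`
and `d = 5|Δ stream| ms`.  Three variants are supported: PE+ → PE−
(the full model), I → PE−, and none.  All state is integrated by uniform
forward Euler at `dt = 0.1 ms`; halving dt changes trial-averaged PE− spike
counts by < 3 % (asserted in tests), and the constant-current spike time
matches the closed form `-tau_m ln(1 - V_th/(R_m I))` within one step.
The model is deterministic: the only randomness anywhere is the order of
the stimulus sequence.

### Intra-module synaptic weights (calibrated, not copied)

The per-synapse weights and delays inside a module are not published, so
they are the package's own calibration.  An automated routine
(`peons.circuit.verify_calibration`) asserts five qualitative constraints on
3-trial probe simulations: (i) a full-strength unexpected tone makes PE+
fire; (ii) an established prediction silences PE+ via I+; (iii) prediction
input alone makes PE− fire; (iv) sensory input silences PE− via I− during
tone delivery; (v) the lateral excitatory weights at stream distance 1–2
exceed the intra-module inhibitory weight onto PE−, so neighbouring streams
can overcome local inhibition.

These constraints still leave a family of workable tables, and much of the
remaining freedom controls one dynamical knife edge: at simulation onset
every PE+ fires, every PE− is bombarded laterally (a single 1.2-µA lateral
EPSC holds PE− above threshold for ~24 ms ≈ 11 refractory-limited spikes),
and with the 0.001/0.0003 increment ratio the prediction gains can deadlock
at zero.  The frozen defaults (I→PE+ 0.30 µA with a 6-ms delay so that
disynaptic feedforward inhibition arrives first; P→I+ 0.10; I+→PE+ 0.40;
P→PE− 0.15, 6-ms delay; I→I− 0.12; I−→PE− 0.28; interneuron delays 1 ms)
were selected from the constraint-satisfying family for the regime in which
predictions establish gradually and monotonically in the standard tone's
streams, omission responses grow gradedly with probability, and the
deviant-tone response pattern emerges — the published behaviour of the
circuit.

### Known limitation: the I → PE− variant's tone correlations

In the alternative I → PE− wiring, the stream-2 PE− neuron's Tone-B drive
comes from sensory neurons whose firing is identical on every Tone-B trial;
the response saturates at a fixed spike count and its correlation with
Prob(A) is undefined (reported as 0 and flagged).  The published negative
Tone-B correlation for this variant is attributed to sub-threshold
membrane-potential carryover between trials slightly altering sensory spike
output; the carryover exists in this implementation too (~0.1 mV at the
next onset) but is far below what uniform forward-Euler threshold crossings
at dt = 0.1 ms can convert into spike-count variability.  The
corresponding acceptance assertion is intentionally left failing rather
than tuned around.

## Model analyses

`probability_sweep` runs one fresh network (predictions zeroed) per
Prob(A) ∈ {0, 0.05, …, 0.95} with omissions fixed at 5 % and 500 stimuli
per condition, pooling 500 omission trials and 4,750 trials per tone;
per-trial responses are full-trial spike counts of the stream-2 PE− neuron
(the response window is configurable; no window is published for the model
firing rates).  Spearman is used for all three trial types (the tone
correlations are labelled *r* in places by the source study; Pearson values
are reported alongside).  Steady prediction gains average the final two
thirds of the trace (25–75 s at full length).  The benefit analysis uses a
1 %-step grid and defines contrast as `10·log10(P2/P1)` — a power-like
reading of the "logarithmic ratio"; zero gains are floored at machine
epsilon and flagged, which in practice affects only the degenerate
Prob(A) = 0 corner where stream 2 receives no input in either variant.
The sensory-adaptation comparison sweeps the 12 combinations of
a ∈ {0.01, 0.05, 0.1, 0.5} and b ∈ {0.1, 0.3, 0.5}; the decaying-exponential
form `S = (1−b)e^{−prob/a} + b` is adopted (adaptation must reduce gain
with exposure, decaying toward the base factor b).

## Recording analysis pipeline

Omission and tone responses are the firing rate in `[onset+5, onset+120)` ms
minus the local baseline rate in `[onset−24, onset+5)` ms (half-open
windows).  Per-neuron probability correlations are computed at the *trial*
level (up to 200 omission trials per training split for 8 conditions), not
on 8 condition means: with n = 8 the reported cluster-mean coefficients
could never reach significance, so the per-neuron test must be trial-level.
The preferred (O_P) tone is the one whose probability correlates
positively; because Prob(B) falls exactly as Prob(A) rises, this is the
sign of the correlation against Prob(A).

Classification is split-half: the odd-indexed (1st, 3rd, …) omission trials
of each condition train, the even-indexed test, 25/25 per condition.
A neuron is a PEON when (1) the training-split Spearman correlation is
significant at p < 0.05 and (2) a one-sample Wilcoxon sign-rank test of the
pooled training omission responses in the four O_P-standard conditions
(probability ≥ 0.75) is significant.  The Wilcoxon test is one-sided
(greater): the criterion asks whether post-omission activity *exceeds* the
immediately preceding baseline.  scipy's implementation is used (exact
null for small samples without ties, normal approximation with continuity
correction otherwise; zero differences discarded).  Tone responses are
subsampled to 50 trials per condition by every-k-th selection before
split-matching, which equalizes statistical power across conditions.
The tone-response significance test behind the selectivity categories
mirrors the omission criterion (the source analysis does not name its tone
test).

Buildup fits bin omission responses by sequence position (bin width 50
items — a width is not published; it is configurable) and fit the logistic
by nonlinear least squares; adaptation fits use the first 50 presentations
of the standard tone *without* subsampling, since every-k-th selection
would discard the early-trial transient that the fit exists to capture.
Exponential fits start from three initial decay rates and keep the best
least-squares solution, which avoids the flat local minimum where the
transient term dies.

The WCSS knee for k-means uses the maximum perpendicular distance to the
chord from k = 1 to k = 10 after normalizing both axes to [0, 1] (raw-axis
distances would be dominated by the WCSS scale).  The enrichment bootstrap
permutes PEON labels across neurons — equivalently, a multivariate
hypergeometric draw of the PEON set per iteration (300,000 by default) —
because the observed statistic is the count of a fixed-size subset; the
two-sided p is the fraction of null counts at least as far from the null
mean as observed, floored at 1/n_boot.  Strata (penetrations) are not
modelled.  The split-overlap expectation `n1·n2/N` equals the
hypergeometric mean (cross-checked against exhaustive enumeration in
tests), with an upper-tail hypergeometric p for the observed overlap.

## Synthetic recordings

The generator emulates exactly the statistical structure the pipeline
tests for: Poisson baseline spiking at 5 spikes/s; tone responses with a
fast exponentially adapting transient (rate 2.25 per presentation, echoing
the published adaptation fit) plus a steady component that decreases
linearly with the tone's probability (deviance structure); and, for
planted PEONs, omission responses in the 5–120 ms window whose amplitude is
20 spikes/s × Prob(O_P) × a logistic in sequence position (rate 0.012,
midpoint 223, echoing the published buildup fit).
Non-selective PEONs (25 % of planted PEONs by default) additionally respond
to the other tone's omissions at 0.35× the primary amplitude: sub-dominant,
because a non-selective PEON must *remain* a probability encoder for its
preferred tone (that is how the real ones passed the correlation
criterion), yet large enough for the selectivity Wilcoxon to detect.
Depths are uniform over 0–1400 µm with the standard laminar bands;
cortical fields are drawn A1/VAF/AAF at 50/25/25 %.

What passing tests on this generator do **not** show about real data:
Poisson trains have no refractoriness, no spike-sorting artefacts, no
cross-neuron correlations, no slow state drift (a sinusoidal baseline
modulation exists but is off by default), and the planted response families
are exactly the parametric forms the pipeline fits.  Recovery scores on
synthetic data are therefore upper bounds on real-data performance.

## Problem sizes

Default sizes were chosen so every analysis is a desk-scale computation:
model sweeps use 500-stimulus conditions (75 s of simulated time each,
~0.2 s wall time per condition), the benefit analysis uses the 1 %-step
grid (192 simulations), the adaptation comparison a 6-point probability
grid (216 simulations), and synthetic recordings 200 neurons over the
eight 1,000-item conditions.  All are parameters of the respective
functions and scripts.
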