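# Methods

This note records the scientific and numerical choices behind `ecgtfmap`:
what each stage assumes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Signal model and preprocessing

Records are 12 × N matrices in millivolts at a sampling frequency fs
(default 500 Hz), in the fixed lead order I, II, III, aVR, aVL, aVF,
V1–V6. The first label of a multi-label record is treated as *the* class
throughout training and evaluation. Records shorter than 6 s are accepted
with a warning: the 6 s floor is a property of the emulated corpus, not of
any algorithm here.

Filtering is a 4th-order Butterworth band-pass, 0.5–50 Hz, applied
forward–backward (`sosfiltfilt`) so the QRS complexes are not displaced by
group delay — R-peak indices detected on the filtered signal can then be
shared across leads and stages. Only the band edges are fixed by the
analysis design; the realisation (order, zero-phase) is this package's
choice of a standard, phase-preserving filter.

## R-peak detection

Detection runs on filtered lead I only; the indices are reused for all 12
leads.

*Pan–Tompkins*: 5–15 Hz band-pass, five-point derivative, squaring,
150 ms moving-window integration, adaptive dual thresholds
(0.125 / 0.875 running updates, acceptance at noise + 0.25·(signal −
noise)) with search-back over gaps longer than 1.66 × the running RR
average. These internal constants follow the classic formulation.

*Shannon energy*: the input is band-limited to 2.5–20 Hz (the
differentiator amplifies wide-band noise, which would lift the envelope
floor between beats), differenced, normalised to unit peak, transformed
as −v²·log v², and smoothed with a 120 ms rectangular window; peaks are
picked above 0.35 × the 98th percentile of the envelope with a 200 ms
minimum separation. The logarithm compresses amplitude differences, so
wide, low-slope QRS complexes (ventricular ectopy) keep enough envelope
mass to be found — the squaring stage of Pan–Tompkins suppresses exactly
these, which is the reason both detectors are combined. On synthetic PVC
records the package reproduces this division of labour: Pan–Tompkins
misses the wide premature beats, the Shannon detector finds them.

Both detectors relocate candidates to the largest-|amplitude| sample
within ±50 ms, and the combined detector merges the union of both
candidate sets, collapsing pairs closer than the 200 ms physiological
refractory period onto the larger-amplitude member. The exact fusion
logic was an open design point; union-then-merge is the reconstruction
that makes the combined sensitivity at least that of each detector alone,
and the suite asserts that property.

## Three-beat windows and representative selection

Windows span R_i − 0.25·medRR to R_{i+2} + 0.5·medRR (medRR = median RR
interval), which includes the P wave before the first R and the T wave
after the last; the margins are this package's choice, picked for that
coverage. Windows slide by one beat (n − 2 windows for n peaks); disjoint
tiling is available as an option. Each window is resampled per lead to
L = 1000 samples (≈ 2 s at 500 Hz) by linear interpolation so that
windows of different heart rates are comparable as fixed-length vectors.

K-means with k = 2 operates on the flattened 12 L-vectors with Euclidean
distance and no per-lead weighting. Because the selection rule's contract
is a *minimum*-SSE two-way partition, instances with n ≤ 12 windows are
solved exactly by subset enumeration on the Gram matrix (2^(n−1) − 1
candidate partitions, O(n²) each); larger instances use k-means++
initialisation with Elkan's triangle-inequality acceleration — a pure
speed-up that cannot change the converged partition — keeping the best of
10 seeded restarts. The test suite checks the exact-minimum property
against a brute-force oracle.

The ratio rule: with r = |small| / |large|, r ≤ 0.35 selects uniformly
(seeded) from the small group, r > 0.35 from the large group; an equal
split triggers one further two-way split of each group, and the smallest
of the four subgroups supplies the draw (ties broken by lowest group
index). Recursion is capped at depth 2, after which the large-group rule
applies. Every decision (group sizes, ratios, branch, candidate pool,
draw) is recorded in a trace, since this rule is the part of the pipeline
most worth auditing.

Why the rule works on episodic arrhythmias: each abnormal beat
contaminates up to three sliding windows. If premature beats were
scattered independently at 20 % of beats, about half of all windows would
contain one and the "abnormal minority" premise would fail; emitted as
one contiguous episode (which is also what an episodic arrhythmia looks
like), k premature beats contaminate only k + 2 windows, so records of
roughly 45 beats or more keep the abnormal windows at ≤ ~26 % of windows
— inside the 0.35 ratio. The selection-purpose test therefore uses 50 s
records at 60 bpm; at those conditions the selected window contains an
abnormal beat in ≥ 90 % of seeded runs (100 % observed).

## Time–frequency maps

Per lead: STFT with 300-sample (600 ms) Hann segments and 270-sample
(540 ms) overlap — i.e. a 30-sample hop — one-sided magnitudes normalised
by the window sum. The stated hop/overlap wording is ambiguous between
"hop = 270" and "overlap = 270 (= 540 ms)"; the 540 ms reading is
implemented as the default and the other is available via
`StftParams(overlap_is_hop=True)`. The frequency bin spacing is
fs / 300 ≈ 1.667 Hz; bins with centre frequency in [0, 50] Hz are kept
(31 bins). The Hann taper, the magnitude (rather than power or dB) scale,
and per-map min–max normalisation are package choices where the analysis
design is silent; normalisation maps constant spectrograms to zeros
rather than dividing by zero. The 12 per-lead 31-row blocks are stacked
contiguously (372 rows) and resized to 120 × 120 by separable linear
interpolation without anti-aliasing pre-filtering (a plain resize).

## CNN classifier

The architecture table is in the README. Open points resolved here:
batch-norm sits between convolution and ReLU; padding is "same"
(TensorFlow convention, extra padding bottom/right) so the group
arithmetic 120 → 60 → 30 → 15 → 8 holds; the head is a single softmax
dense layer directly after flattening (a config hook allows hidden dense
layers); batch size defaults to 32. L2 regularisation is Keras-style:
λ·Σw² added to the loss, 2λw to the gradient, on conv kernels and biases
only. No class re-weighting or resampling is applied — imbalance is
handled at evaluation time through the weighted metrics.

The network is implemented in NumPy in float32: im2col convolutions with
matmul forward passes, shift-and-add scatter for the input gradient,
standard batch-norm backward, inverted dropout, and Adam
(β₁ 0.9, β₂ 0.999, ε 10⁻⁷). Each layer's backward pass is verified
against finite differences in the suite, and the trainable-parameter
count (95 065 for the default configuration) is checked against a
closed-form layer-arithmetic oracle.

Training: stratified 80/20 train/test split, then stratified k-fold
cross-validation (default 5) on the training portion with a fresh
re-initialisation per fold; the fold with the lowest validation loss is
retained, and the untouched 20 % supplies the evaluation report. The
default epoch budget is 500; desk-scale runs (tests, smoke pipelines) use
reduced epochs and 2 folds, which is a problem-size choice of this
package's test suite — the separable two-class check reaches ≥ 0.95
training accuracy with 30 epochs of the full-width architecture.

## Evaluation

Metrics come from one-vs-rest confusion-matrix counts; specificity is
TN/(TN+FP). Zero denominators yield 0 with an explicit `undefined` flag
rather than NaN. Macro is the unweighted column mean; weighted uses
W_class = n_class / n_total. ROC AUC is trapezoidal; PR AUC is the
step-wise threshold-sweep integral (average precision), not an
interpolated variant. The suite verifies ROC AUC against the
Mann–Whitney pair-counting statistic and checks that macro-averaging the
per-class columns of the published reference summary table reproduces its
printed macro row (F1 0.74, AUC-ROC 0.85, AUC-PR 0.79 at two decimals).
Display rounding is two decimals; full precision is kept internally.

## Synthetic data: what it does and does not show

Each beat is a sum of five Gaussians (P, Q, R, S, T) with a fixed 12 × 5
per-lead gain table (rS pattern in V1–V2, inverted aVR, lateral R
dominance). Class signatures: AF removes P, forces RR coefficient of
variation ≥ 0.25 and adds a band-limited 5.3–10 Hz fibrillatory
oscillation; I-AVB moves P so the PR interval exceeds 200 ms on every
beat; LBBB widens the QRS (≥ 120 ms) with an M-shaped notch strongest in
I/aVL/V5/V6; RBBB adds an R′ in V1/V2 and a slurred wide S laterally;
PAC/PVC make a contiguous 20 % episode of premature beats (preceding RR
shortened 40 %, compensatory pause after), PVC beats additionally P-less,
wide (120–210 ms), tall, with discordant T; STD/STE offset the ST segment
by ∓/± 0.1 mV (all beats by default, a minority fraction configurable).
Baseline wander (0.25 Hz sinusoid) and white noise are added; a helper
injects noise at an exact SNR. Everything is reproducible bit-for-bit
from the seed, and the generator returns exact R locations and per-beat
tags.

What this emulates well: the morphological contrasts the pipeline keys
on, beat timing statistics, and controlled noise levels. What it does not
emulate: torso-model lead physics, inter-patient variability, electrode
artifacts, pathological axis shifts, or multi-arrhythmia records. Tests
passing on this generator therefore demonstrate that the pipeline's
mechanics behave as specified — not that clinical-grade accuracy carries
over to real corpora, which would require the real data and full-scale
training runs that are outside this package's scope.

## Known limitations

- Frequencies above 50 Hz are discarded by design; arrhythmias expressed
  there are invisible to the features.
- The exact-partition path bounds K-means optimality only up to 12
  windows per split; beyond that, restarts make global optimality highly
  likely but not guaranteed.
- The NumPy CNN is single-threaded and desk-scale; it is not intended for
  full-corpus training.
- WFDB support covers format 16 only (the common 12-lead case), not the
  full family of WFDB sample encodings.
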