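# Methods

## Problem

High-frequency oscillations (HFOs, 80–500 Hz) are brief oscillatory bursts in
electrophysiological recordings that mark epileptogenic tissue. In MEG
practice a ~1 h, 306-channel recording at 2,400 Hz is cut into 2-s windows
(4,800 samples), windows without appreciable high-frequency content are
discarded, and a reviewer labels the survivors. This package automates the
two downstream tasks: *detection* (classify a candidate window as HFO vs.
normal control, NC) and *recommendation* (rank a patient's windows by
predicted HFO probability and surface the top N for review).

## Detector

Every variant shares a dense front end mapping the input window to 512
features, reshaped into n = 8 tokens of width d = 64. The attention blocks
use *additive* scoring: token x_i receives a scalar score

    f(x_i) = wᵀ σ(W¹ x_i),      σ = tanh by default,

scores are softmax-normalized into importance weights p(z=i|x), and each
token is re-weighted, y_i = p(z=i|x) · x_i. The multi-head form runs k = 8
such scorers on learned d/k-dimensional projections of the token sequence,
concatenates the re-weighted heads and mixes them with an output matrix W^O.
The query-conditioned form f(x_i, q) = wᵀσ(W¹x_i + W²q) is exposed as a
primitive but unused by the detector (self-attention drops the query).

Variants: `raw`/`smo` (no attention; dropout → dense 512 → dense 128 → batch
norm → dense 32 → batch norm → sigmoid), `attn_1` (multi-head block only),
`attn_2` (single full-width self-attention only), `msadr` (multi-head then
single). Attention variants insert batch norm + tokenize + attention +
flatten between the front end and the dense-128 head.

**Re-weighting, not pooling.** The final attention stage re-weights tokens
(keeping n × d, flattened afterwards) rather than pooling them to a single
d-vector. Re-weighting is the literal reading of "the weighted element
according to its importance"; it also keeps the post-attention head identical
across all four variants, so each ablation strictly *removes* parameters
(2,528,257 < 2,533,441 ≤ 2,538,049 < 2,542,209 for raw < attn_2 ≤ attn_1 <
msadr at default widths). The weighted-*sum* pooling form remains available
as `self_attention_pool`.

Training minimizes binary cross-entropy, L = −y log p − (1−y) log(1−p) with
p clipped to [1e-7, 1−1e-7], by mini-batch Adam (lr 1e-4, batch 32, 10
epochs). Softmax uses max-subtraction. The network is plain numpy with
hand-written backpropagation; analytic gradients of every layer are verified
against central finite differences in the test suite (float64, rel. 1e-4).

### Input representation

The detector consumes, by default, the **amplitude spectral density of the
80–500 Hz band** of the window (Welch estimate, Hann windows of 400 samples
with 50 % overlap → 6 Hz resolution, ~70 bins, square root of the PSD).
Rationale: an oscillatory burst occurs at arbitrary position and phase within
its 2-s window, so the raw waveform carries no first-order (linear)
class structure — a dense front end trained for 10 epochs memorizes instead
of generalizing. The band-restricted spectrum is position- and
phase-invariant and makes band energy linearly accessible; it is also
consistent with the screening step, which already defines 80–500 Hz as the
candidate band. The raw/band-passed waveform remains available via
`ModelSpec(input_repr="waveform", input_filter=...)` and the experiment
runner can sweep representations. Inputs are standardized by the training
set's global mean and standard deviation (stored in the checkpoint).

### Defaults that matter

| parameter | default | why |
| --- | --- | --- |
| heads k | 8 | the published sweep's best value; d = 64 divides all of {2,4,8,16} |
| tokens n × d | 8 × 64 | factorization of the 512-wide front end divisible by every swept k |
| dropout p | 0.05 | unstated upstream; with ~70 spectral inputs, heavy input dropout deletes the sparse informative bins (chosen on validation folds from {0, 0.05, 0.1, 0.2}) |
| learning rate / epochs / batch | 1e-4 / 10 / 32 | published training settings, also used for MSADR |
| normalization | batch norm, momentum 0.9, running stats at inference | the cited normalization is batch normalization; inference is batch-size invariant |
| optimizer | Adam | unstated upstream; the standard choice for this family |
| attention σ | tanh | the conventional additive-attention nonlinearity; ReLU available |
| decision threshold | 0.5 | fixed; ranking never thresholds |

## Simulator

Real gold-standard HFO data is clinical and unavailable, so the package
simulates it. One channel of background is 1/f^β noise (β = 1, synthesized in
the frequency domain with expected-power normalization, PSD =
`pink_scale²/f^β`, `pink_scale` = 300 units/√Hz at 1 Hz) plus a white sensor
floor (amplitude spectral density `noise_floor` = 4 units/√Hz, i.e. per-sample
σ = noise_floor·√(fs/2)). The pink default keeps the neural background
dominant over the sensor floor throughout 10–500 Hz, as in real MEG;
amplitudes are arbitrary-but-consistent units (absolute femtotesla
calibration is irrelevant to classification).

An HFO is a Gaussian-windowed sinusoid (±3σ support): carrier ~ U(band),
duration ~ U(30, 100) ms, random phase, draws with fewer than 4 cycles
rejected (the conventional minimum-cycle definition). SNR is defined as
burst power over background power *within the burst band and over the burst
support* (background band power measured by zero-phase Butterworth
band-pass); default 10 dB. The gold standard balances 660 HFO + 660 NC
windows over 20 patients, patients assigned round-robin within each class so
per-patient counts are exact (66 per patient, 33 per class). Long recordings
inject bursts at Poisson times on random channels, with an event table of
(channel, onset, offset, band).

No value for burst amplitude, duration or SNR statistics of real
expert-labeled HFOs is published; the defaults above are documented
stand-ins. The simulator also omits epileptic spikes, muscle/cardiac
artifacts, head movement, inter-channel correlation, and source geometry —
passing tests therefore demonstrate correctness of the pipeline and
learnability of a band-limited-burst task, not clinical performance.

Determinism: every operation is a pure function of (config, seed); each
operation draws from its own named stream derived from the seed, so adding
operations never perturbs existing draws. With default SNR the band-power
(80–500 Hz) distributions of HFO and NC windows separate with AUC ≈ 0.98,
so the detection task is learnable by construction.

## Preprocessing

Band-pass filters are 4th-order Butterworth applied forward-backward
(zero-phase, length-preserving); presets `ripple` (80–250), `fast_ripple`
(250–500) and `screen` (80–500). Segmentation uses half-open windows
[start, start+W) with step = round(W·(1−overlap)); trailing samples are
dropped. The candidate screen keeps a window iff its 80–500 Hz power is at
least `ratio_threshold` (default 0.1) of its 1–500 Hz power, by periodogram
integration — it stands in for the source-level goodness-of-fit filters of
the clinical pipeline, which require dipole fitting that is out of scope.

EDF files are written by a minimal 16-bit encoder (physical range per
channel, blank physical dimension so values round-trip unscaled, record
duration shrunk below 1 s when 306 channels would exceed the EDF record-size
cap) and read through `mne`; a delimited text fallback (one column per
channel) is supported for interchange.

## Evaluation

*Detection*: stratified 10-fold cross-validation over pooled segments
(90/10); confusion counts pooled over folds before computing accuracy,
recall, precision and F (micro-average; per-fold metrics also reported).
The "10-fold leave-one-out" phrasing in the source material is
self-contradictory; the 90/10 description is what is implemented.
Segment-level stratification permits the same patient on both sides of a
split — that is the published pooled protocol — and a strict
`patient_holdout` detection mode is available. Undefined ratios
(zero denominators) are reported as missing, never as 0.

*Recommendation*: patients are shuffled once (seeded) and partitioned into
10 folds (2 held-out patients per fold with the 20-patient cohort; every
patient tested exactly once). Each held-out patient's windows are ranked by
probability — descending, ties broken by ascending segment id — and
P@N = (true HFOs in top N)/N is computed for N ∈ {1, 3, 5}, averaged over
patients within a fold and then over folds; the patient-first grand mean is
reported alongside since the published aggregation order is unstated.

## Problem sizes

The shipped benchmark (test suite and acceptance script) runs the full-size
synthetic cohort — 1,320 segments, 20 patients — with 10-fold detection,
10-fold patient-holdout recommendation and the no-attention ablation,
reporting the median over 3 simulation/training seeds; unit tests use 80-
to 200-segment sets. These sizes were chosen so the whole suite completes in
a few minutes on a single CPU while keeping every protocol at its full fold
and cohort structure.

## Known limitations

- The published clinical results (accuracy 0.886, P@1 0.967 on private MEG
  data) are not reproducible here and are not targets; the synthetic
  benchmark measures the pipeline, not the clinic.
- The published parameter counts (e.g. 411,325 for the full model) imply an
  input representation that was never described; they are not matched.
- The detector requires fixed-length windows; it does not localize burst
  onset/offset within a window.
- Baselines (RF, linear SVM) are thin scikit-learn delegates with the
  published hyperparameter grids; they see the same input representation as
  the network.
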