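# Methods

This note documents the models, numerical choices and synthetic study
conditions implemented in `p300tl`, and what the package's tests do and do
not demonstrate.

## Signal model and preprocessing

Continuous EEG is represented as a (time × channels) array in microvolts
with a stimulus event table (onset sample, flash code, target flag,
character and repetition indices). Preprocessing is deliberately minimal,
matching common ERP practice:

- **Band-pass filter**: 4th-order Butterworth applied forward–backward
  (zero-phase), 0.1–30 Hz for the speller and 0.15–28 Hz for RSVP. The
  filter order refers to the analog prototype; zero-phase filtering squares
  the magnitude response. Because the low cutoff creates transients lasting
  on the order of 1/low seconds, the reflect-padding length is set to
  3·fs/low samples (capped at the signal length) rather than scipy's
  default, which is orders of magnitude too short for a 0.1 Hz edge.
- **Downsampling**: polyphase FIR anti-alias filtering with integer
  decimation (2048 Hz → 64 Hz for RSVP-like recordings); event onsets are
  remapped by the decimation factor and rounded.
- **Epoching**: the half-open window [0, d) seconds after each event onset,
  with T = round(d·fs) samples. This reproduces both canonical shapes:
  0.665 s at 240 Hz → 160 samples, 0.7 s at 64 Hz → 45 samples (44.8
  rounded up). Events whose window would run past the end of the recording
  are dropped and counted in a log message. No baseline correction,
  re-referencing, channel selection or artifact rejection is applied.

## The CNN

The network is implemented directly in numpy (im2col convolution, explicit
backward pass) — the sizes involved (≤ 160×64 inputs, ≤ 128 features) make
framework-scale machinery unnecessary and keep training bit-reproducible
from a seed on any machine.

Architecture for a T×C epoch: per-channel batch-norm on the input;
convolution with K kernels of shape [kernel_height × C] and temporal stride
S (kernel_height = round(T/10); K = S = 16, f = 128 for the 160×64 speller
configuration; K = S = 5, f = 36 for the 45×8 RSVP configuration);
per-kernel batch-norm; ReLU; the flattened K·positions activations feed a
dense layer of f units (ReLU) and a dense layer of 2 units with softmax.
The conv output for the canonical configurations has
(T − kernel_height)/S + 1 = 10 (speller) or 9 (RSVP) positions. The
conv-to-dense connection is a full dense map of the flattened activations.

Training: SGD with learning rate 0.01, momentum 0.9, L2 weight decay 5·10⁻⁴
on the three weight matrices (not biases or batch-norm parameters),
cross-entropy loss, batch size 64. Batch-norm uses batch statistics during
training and running statistics (momentum 0.1) at inference, so inference
is independent of batch composition. Because the number of training epochs
is a free choice, the trainer runs up to `max_epochs` (default 100) with
early stopping (patience 10) on a 10% held-out validation split and returns
the parameters with the best validation loss. The analytic gradients,
including both batch-norm layers, are validated against central finite
differences in the test suite (relative error < 10⁻⁴).

**Fine-tuning** freezes the "front end" — input batch-norm, convolution and
post-conv batch-norm, i.e. the generic feature extractors — bit-exactly:
frozen batch-norm layers run in inference mode during fine-tuning and
receive no statistic updates, so their parameters and buffers are identical
before and after. Only the two dense layers adapt to the target subject.
Class imbalance (1:5 speller, 1:9 RSVP) is not reweighted.

**Features** are the post-ReLU activations of the first dense layer
(nonnegative, dimension f). A switch (`layer="conv"`) exposes the flattened
post-ReLU convolution output instead, for experiments on which stage's
features to align; all defaults use the dense-layer features.

## Euclidean alignment

The reference matrix is the mean outer product of the feature vectors
(uncentered second moment — exactly as defined, not the mean-centered
covariance). The whitening map is computed by symmetric eigendecomposition
of R̄ + εI with eigenvalues floored at ε, giving a symmetric W with
W(R̄+εI)W = I to ~10⁻¹² relative error. ReLU features are frequently
rank-deficient (dead units, correlated activations), so ε defaults to the
scale-aware ridge 10⁻⁶·trace(R̄)/f; it vanishes relative to the spectrum in
the well-conditioned limit. The online mode maintains the running mean
R̄ₙ₊₁ = (n·R̄ₙ + yyᵀ)/(n+1) and recomputes W each trial (f ≤ 128 makes this
negligible); after a full stream it equals the offline reference exactly up
to floating-point association. No forgetting factor is used. Source and
target (and, at test time, the test stream) each use their own reference.

A caveat observed with scaled-down synthetic data: whitening amplifies
near-dead feature directions by ε^(-1/2), and with few trials per feature
dimension the train and test reference estimates disagree; alignment is
most effective when N/f is comfortably large, which informed the benchmark
sizes below.

## Source sample selection

The target reference r is the arithmetic mean of the aligned target
features; source samples are ranked by the Euclidean norm ‖r − ỹᵢˢ‖ (the
squared distance gives the same ranking) and the k smallest are kept, ties
broken toward the lower source index via a stable sort, making the
selection deterministic. k is a configuration parameter: the pipeline's
default keeps 50% of the source samples. The selection is validated against
a brute-force full-sort oracle and recovers a planted 50/50
matched/shifted source mixture with precision ≥ 0.95 when the shift
dominates the noise.

For multi-subject pools, performance-based subject selection trains one
classifier per candidate source subject (the classifier is injected as a
callable, since nothing constrains it to be the CNN) and keeps the subject
scoring highest on the last 20% of the target calibration trials in session
order; ties go to the lowest subject id.

## Discriminative RBM

For a joint RBM over (features x, one-hot label y, binary hidden h), the
hidden layer marginalizes analytically, giving the exact conditional
p(y|x) ∝ exp(b_y + Σⱼ softplus(cⱼ + U_jy + Wⱼ·x)), evaluated with
log-sum-exp for stability. Training maximizes the mean conditional
log-likelihood by minibatch gradient ascent with the exact analytic
gradient — no contrastive divergence or sampling anywhere. Defaults: 10
hidden units, learning rate 0.05, 200 epochs, batch 128, N(0, 0.01²)
initial weights, zero biases, all seed-controlled. Features are used as
real values (the conditional never requires binary inputs). A
generative-objective mixing weight `alpha` is exposed for hybrid
discriminative/generative training but only `alpha = 0` is implemented;
a nonzero value raises `NotImplementedError`. The conditional is verified
against explicit enumeration of all 2^H hidden configurations, and the
gradient against finite differences.

## Decoding and metrics

- **Character decoding**: per flash code (1–6 rows, 7–12 columns), target
  probabilities are summed over the first Nr repetitions; the decoded cell
  is (argmax rows, argmax columns), ties toward the lower code. Summation
  (equivalently averaging) of probabilities was chosen as the fusion rule;
  a constructed counterexample in the tests distinguishes it from
  majority-vote decoding. The 6×6 matrix is A–Z then 0–9 row-major and is
  configurable.
- **ITR**: bits = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)) with N = 36,
  the 0·log 0 convention at P ∈ {0, 1}, selection time
  T = 2.5 + (0.100+0.075)·12·Nr seconds, ITR = 60·bits/T bpm. Reported
  values are rounded to one decimal; accuracy curves are reported in
  percent (integer rounding, half-up, where tabulated).
- **BCA** = (n₁/m₁ + n₂/m₂)/2, prevalence-invariant by construction.

## Synthetic study conditions

The generator emulates the two paradigms' stimulus schedules exactly
(12 flashes per repetition with one target row and one target column code;
RSVP streams at 5 stimuli/s with round(n·0.1) targets) and the following
signal ingredients:

- P300 template: Gaussian bump, peak 0.3 s post-stimulus, FWHM 0.2 s,
  amplitude 5 µV, per-channel weights; per-flash latency jitter (Gaussian,
  default sd 20 ms) and a per-subject latency offset.
- Background noise: per-channel AR(1) (coefficient 0.95) plus white noise,
  summed standard deviation = `noise_scale` µV — a two-parameter stand-in
  for the 1/f-heavy spectrum of resting EEG.
- Cross-subject shift: invertible channel mixing × gain. Two families are
  provided: fully random orthogonal mixing, and a "mild" variant
  (matrix exponential of a scaled skew matrix, rotation ≤ 0.3 rad, gain
  0.5–2) representing subjects sharing a montage.

What the generator does **not** model: real electrode topographies and
volume conduction, eye/muscle artifacts, non-stationary drift within a
session, and realistic ERP component mixtures. Consequently, passing tests
demonstrate correctness and the direction of each pipeline stage's effect
under controlled shift and noise — not the accuracy levels attainable on
real competition data, which this package does not ship.

### Benchmark scenarios

`p300tl.benchmarks` freezes two scenarios used by the tests and docs:

- **Noise-free speller pair** (zero noise and jitter, identity shift,
  8 channels at 120 Hz, f = 16 network): the full pipeline must decode
  100% of held-out characters at the maximum repetition budget — an
  end-to-end correctness oracle.
- **RSVP transfer pair**: target subject with 200 calibration trials and
  480 test trials at noise 8 µV; source subject (mild shift, noise 5 µV)
  whose session is half clean and half corrupted — the corrupted block has
  no ERP under its target labels and 3× noise, emulating an inattentive,
  artifact-laden recording stretch. The corrupted trials are what makes
  source *selection* meaningful: their labels actively mislead a classifier
  (negative transfer), while their elevated noise displaces them in feature
  space so distance-based selection at k = 50% prunes them. With ~20
  target-class calibration trials, a target-only classifier is starved,
  which is what makes *alignment + source data* meaningful.

  Over seeds 1–10 the mean test BCA of the four ablation variants is
  ordered scratch ≤ fine-tune ≤ fine-tune+EA ≤ fine-tune+EA+selection
  (the acceptance test asserts exactly this ordering of means). Individual
  seeds are noisy — several are degenerate at BCA 50 when the 1:9
  imbalance defeats every variant — which is why the claim is about the
  multi-seed mean, not per-seed dominance.

Problem sizes throughout (characters, trials, channels, f, training
epochs) are chosen so a full multi-seed ablation runs in well under a
minute on one CPU while keeping N/f large enough for stable reference
matrices; they are scaled-down analogues, not replications, of the
full-size paradigms.

## Known limitations

- The DRBM trainer has no class reweighting; under 1:9 imbalance with very
  few positive examples it can collapse to the majority class (visible as
  BCA 50 in some benchmark seeds). This mirrors the plain conditional
  likelihood objective.
- The hybrid (generative+discriminative) DRBM objective is exposed but not
  implemented.
- Online alignment recomputes the eigendecomposition per trial; adequate
  for f ≤ 128, not tuned for larger feature widths.
- Adapters for real EEG file formats are out of scope; recordings enter as
  HDF5 arrays plus an event table.
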