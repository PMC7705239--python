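# Methods

## Problem and model

`mnlnet` classifies fixed-length single-channel EEG segments into task
classes defined by a class-combination scheme over the five canonical
recording conditions A–E. A raw record of 4,097 samples (23.6 s at
173.61 Hz) is cut into 23 contiguous chunks of
⌊4097/23⌋ = 178 samples; the 3 trailing samples are discarded. This
truncation rule is forced by the corpus arithmetic (23 × 100 × 5 = 11,500
segments of length 178) and is the only rule consistent with both the
per-set counts and the per-segment CSV layout. Each chunk is z-scored
independently with the population standard deviation (divide by *n*);
per-segment normalization makes the pipeline order-independent and
matches the fact that the network input is the segment, not the record.
A constant chunk maps to the zero vector rather than raising. Note the
z-score is unbounded — it centers and scales but does not map into
[0, 1].

The classifier is the MNL network described in the README. Points where
the published description is under-determined, and the choices made here:

* **Convolution padding.** The first stage maps 178 → 178 with kernel 40,
  which forces length-preserving ("same") padding at stride 1; stages two
  and three map 89 → 35 (kernel 20, stride 2) and 17 → 4 (kernel 10,
  stride 2), which forces un-padded ("valid") convolution with floor
  division. Both are fixed accordingly and the shape trace is asserted at
  build time rather than assumed.
* **Signal-pooling output width.** Concatenating the three branches gives
  3*c* channels, while the layer is specified as shape-preserving
  (4 × 80 in, 4 × 80 out). A trainable pointwise convolution (3*c* → *c*)
  reconciles the two; `pooling_reduce="none"` keeps the raw concatenation
  for experimentation.
* **Attention orientation.** The affinity φᵀδ is a ĉ × ĉ
  channel-by-channel matrix — attention over the multi-scale feature
  channels. This literal form is the default; the classical
  position-by-position (w × w) non-local block is available via
  `attention_mode="position"`.
* **Attended-feature shape.** R̂ × ϱᵀ is ĉ × w while the attended output
  must live in ℝ^(w×ĉ); the product is computed as ϱ × R̂ᵀ so the
  declared shape holds.
* **Embedding width.** ĉ defaults to *c*/2 (= 40 at the 80-channel
  stage), the convention of the non-local attention literature;
  configurable.
* **Two fusion convolutions.** The inner (ĉ → *c*, before the residual
  addition) and outer (*c* → *c*, after) pointwise convolutions are
  distinct trainable layers; shared weights would be dimensionally
  impossible whenever ĉ ≠ *c*.
* **Softmax axis.** Row-wise over the affinity matrix, so each output
  channel's weights over source channels sum to one.
* **Batch-norm / activation order.** conv → BN → ReLU, the dominant
  convention; the head width of the final FC layer always equals the
  active task's class count.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 5·10⁻⁴, mini-batch
100, cross-entropy loss. The schedule multiplies the learning rate by 0.1
when the best validation accuracy has not improved for 10 consecutive
epochs, then re-arms; training stops at `max_epochs` (default 100) or
when the learning rate falls below 10⁻⁷. Because the protocol
checkpoints on validation accuracy but the cross-validation design names
only train/test folds, a stratified 10% slice of each fold's training
data is carved out for validation; the test fold is never touched before
final evaluation — any other reading would leak test data. The returned
checkpoint is the epoch with maximal validation accuracy (ties broken in
favor of the earlier epoch).

Folds are drawn over segments, stratified per class with equal counts per
fold (±1), from a seeded generator. Segment-level folding lets chunks of
one record span train and test — that follows the published protocol
literally and is known to flatter accuracy relative to record-disjoint
folding; the `FoldSplit` carries provenance so a stricter split can be
layered on.

The whole stack is NumPy with hand-derived backward passes; single-
threaded execution is deterministic bit-for-bit given a seed, which the
byte-identical-report checks rely on. Gradient correctness is established
by central finite-difference checks over every layer type, including
both attention modes and both batch-norm modes.

## Metrics

Confusion counts are one-vs-rest; the seizure class (last group of a
scheme, index C−1) is the positive/abnormal class for binary tasks.
Multi-class tasks report overall accuracy plus the unweighted (macro)
mean of the one-vs-rest precision, sensitivity, specificity and F1 — the
averaging rule for the published multi-class tables is not stated and
cannot be reverse-engineered uniquely, so macro, the most common
convention, is used and per-class values are always emitted so any other
convention can be recomputed. Zero-denominator ratios evaluate to 0 with
a logged warning so a degenerate fold cannot abort a run. Reports print
percentages at two decimals; JSON keeps raw fractions.

The UCI CSV's integer labels are mapped 1 → E, 2 → D, 3 → C, 4 → B,
5 → A, following the UCI documentation (the seizure class is 1 there);
the mapping lives in one constant table.

## Synthetic surrogate data

The generator emulates the corpus layout (five sets, 100 records per set,
4,097 samples at 173.61 Hz by default) with class-dependent spectral
structure on a 1/f Gaussian background (spectral exponent ≈ 1, unit SD):

| sets | component | amplitude at separability 1 |
|------|-----------|------------------------------|
| A, B | ~10 / ~9 Hz alpha-band rhythm | 0.9 / 0.7 × noise SD |
| C, D | sparse Gaussian transients (0.6 / 1.0 per s) | 2.0 / 2.5 × noise SD |
| E    | 3 Hz spike-and-wave train | 3.0 × noise SD |

Every class-dependent amplitude scales linearly with the `separability`
knob, so at 0 all five sets are drawn from the identical background
distribution (verified by a Monte-Carlo two-sample test on seizure-band
power), and at ≥ 3 the seizure class is nearly linearly separable. One
global seed spawns an independent stream per (set, record), making any
subset reproducible regardless of generation order. Samples are clipped
at a configurable ±50 SD, far outside normal operation.

The surrogate reproduces layout, 1/f background, rhythmic/transient/
spike-wave phenomenology and controllable class contrast. It does not
reproduce the real corpus's amplitude statistics, artifacts, inter-record
heterogeneity, or non-stationarity — so passing pipeline tests
demonstrates that the implementation learns and evaluates correctly, not
that it attains the published accuracies on real recordings. Reproducing
those requires the real corpus (downloadable in the UCI CSV layout and
readable with `read_uci_csv`) under the full 10-fold protocol.

## Problem sizes in tests and acceptance runs

The full-pipeline checks run a scaled study: 25 records per set
(1,150 A-E segments), 3 folds, 20 epochs — chosen as the smallest setting
at which the separable task saturates (mean accuracy ≥ 0.95 with wide
margin) and the null task's chance level is estimated within ±0.05.
Structural properties of the 10-fold protocol (layout, stratification,
fold counts) are tested directly at k = 10 on index-level fixtures.

## Known limitations

* No EDF/BDF readers, multi-channel montages, filtering or artifact
  rejection — the upstream protocol applies none.
* Channel-attention vs position-attention cannot be settled from the
  published text; both are implemented, the literal channel form is the
  default.
* Training is single-threaded CPU NumPy: small tasks train in seconds to
  minutes, but the full 11,500-segment, 10-fold, 100-epoch protocol is a
  multi-hour run.
* The multi-class macro averages need not match the published multi-class
  summary rows, whose averaging convention is not reproducible from the
  printed values under any standard rule.
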