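# Methods

## Signal model and pre-processing

Input records are single-channel EEG traces in microvolts (the Bonn text
dialect: one sample per line, no header, nominally 173.61 Hz, 23.6 s, i.e.
≈4097 samples; both 4096- and 4097-sample copies circulate and both are
accepted). The label and sampling rate are caller-supplied because the
format carries no metadata.

**Windowing.** Given window length *w* and overlap fraction *o*, the hop is
*h* = round(*w*(1−*o*)) and the window count *n* = round((L₀−*w*)/*h*) + 1,
with rounding half away from zero for platform determinism. The record is
then linearly resampled to *w* + (*n*−1)*h* samples so the windows tile it
exactly. This resampling step is what makes the reference configuration
work out: a raw 4097-sample record fits only six 868-sample windows at 1/3
overlap, whereas resampling up to 4342 samples realizes exactly seven.
Resampling is plain linear interpolation with endpoints preserved; the
records are already band-limited well below Nyquist, so no anti-alias
filtering is applied.

**CWT.** The transform is computed in the frequency domain: FFT of the
window, multiplication by the analytic mother wavelet's frequency response
ψ̂(sω) at each scale s, inverse FFT, magnitude. ψ̂ is supported on ω > 0
(analytic), peak-normalized to 1:

| family | ψ̂(ω), ω > 0 | peak ω_c |
|---|---|---|
| morlet | exp(−(ω−6)²/2) | 6 |
| bump | exp(1 − 1/(1−((ω−5)/0.6)²)) on \|ω−5\|<0.6 | 5 |
| gmw | ∝ ω⁶⁰ exp(−ω³) (evaluated in log space) | (60/3)^{1/3} ≈ 2.714 |
| cmhat | ω² exp(−ω²/2) · e/2 | √2 |
| hhhat | ∝ ω(1+ω) exp(−ω²/2) | ≈ 1.249 (numeric) |

Scales are log-spaced so the center frequency ω_c/(2πs) spans from the
Nyquist rate (0.5 cycles/sample) down to two oscillation cycles per window.
The scale **count** defaults to 233 — pinned to reproduce the reference
input geometry — while the range rule above is the package's own choice;
there is no canonical published rule for it. The "physical" versus
"unspecified" sampling-rate modes compute the identical transform; fs only
affects how scales are labelled in Hz.

**Normalization** is per window: each window's scalogram is independently
min–max scaled to [0, 1], so every non-constant window attains both bounds;
a constant window maps to all zeros. This discards absolute amplitude —
classification rests on the time–frequency *pattern*, not on signal power.

An optional bilinear resize stage (e.g. to 250×250) exists but is off by
default: the reference parameter count of 6,981,109 is only consistent
with unresized 233×868 inputs, so the unresized path is canonical here.

## Architecture

Each of the n branches: 3×3 valid convolution with F=10 filters →
ECA gate → ReLU → 2×2 max-pool (floor) → flatten → 2-unit softmax head.
The ECA gate is a bias-free 1-D convolution of length k=3 (zero-padded,
same length) over the per-channel global means, followed by a sigmoid;
it contributes exactly k parameters. The branch heads are concatenated
(length 2n) and classified by dense(432) → ReLU → batch norm →
dropout(0.7) → dense(2) → softmax.

Several micro-choices (valid padding, k=3 bias-free ECA, 2-unit softmax
heads as the merged features, batch norm counted with 4 terms per unit,
ReLU between the gate and the pool) were fixed jointly as the unique
combination under which the closed-form count reproduces 6,981,109 from
the stated layer inventory; each is individually conventional. The
per-branch softmax heads receive no auxiliary loss — they act as bounded
feature layers, trained only through the merge classifier's gradient.

Closed-form count (k = conv kernel, k_e = ECA length, F filters, S×W
input, n branches, H merge units, 2 classes):

    block  = (k²F + F) + k_e + (⌊(S−k+1)/2⌋·⌊(W−k+1)/2⌋·F·2 + 2)
    total  = n·block + (2nH + H) + 4H + (2H + 2)

The built network's array sizes are verified against this formula in the
tests for randomized geometries.

## Training protocol

1. **Pre-train** — every stack of n scalograms is exploded into n labelled
   single-scalogram items (m records → m·n items) and a standalone block is
   trained on them.
2. **Transfer** — the block's convolution, ECA and head weights are copied
   into every branch; the merge layers keep their fresh initialization.
   Transferred layers stay trainable (a `freeze_transferred` switch exists).
3. **Train** — mini-batch cross-entropy training, batch 32, up to 150
   epochs, stopping at the first epoch whose end-of-epoch training-set
   accuracy is 100%. The same early-stop rule governs pre-training.

Optimizers: Adam (β₁=0.9, β₂=0.999, ε=1e−7) and plain SGD; learning rates
from {0.01, 0.001, 0.0001} in the search grid, default 1e−4 with Adam (the
best-performing combination). All randomness — initialization, shuffling,
dropout masks — derives from the training seed through independent
`SeedSequence` substreams, so identical seeds give identical weights,
losses and predictions. In cross-validation, fold i trains with seed
base+i.

Loss is categorical cross-entropy against one-hot labels; batch norm uses
momentum 0.99 and ε=1e−3, with running statistics at evaluation time.

## Evaluation

Ictal is the positive class. Accuracy, precision, recall and F1 follow the
standard confusion-matrix formulas; any zero-denominator metric is
reported as 0 so that fold averages remain defined. The classification
unit is the record (the network consumes all n windows of a record
jointly). Protocols: stratified k-fold (default 10, scikit-learn splitter,
seeded), stratified 70/30 holdout, and grouped leave-one-subject-out,
which requires caller-supplied group identifiers — per-record subject IDs
are not distributed with the Bonn data, so LOSO there is only possible
with external metadata. The "L2" value recorded by the search driver is
the mean squared error between one-hot labels and predicted probabilities
pooled over all validation items.

## Synthetic data

The generator emulates the contrast the classifier exploits, not EEG
physiology (no neural-mass dynamics, no artifacts, no electrode noise):

* *ictal-like*: sinusoid with fundamental drawn uniformly from 3–5 Hz,
  2nd/3rd harmonics at 0.45/0.2 relative amplitude, ±35% amplitude
  modulation at 0.2–0.5 Hz, amplitude scale 800 µV, plus white noise at
  15% of the rhythmic RMS;
* *interictal-like*: 1/f-shaped coloured noise mixed with a weak 8–12 Hz
  rhythm at 200 µV scale.

Records are deterministic in (seed, index) via independent substreams;
datasets are balanced and interleaved, with five pseudo-subjects per class
(index blocks) to exercise grouped splits. By construction the classes are
separable (an RMS threshold alone classifies ≥95% of a default dataset),
so a pipeline that fails to reach high held-out accuracy on this data is
broken; conversely, passing says nothing quantitative about performance on
real EEG, where class overlap, artifacts and non-stationarity dominate.

## Problem sizes

The test suite and the end-to-end checks run a scaled profile chosen as
this package's desk-scale configuration: 200 records of 1024 samples,
64 scales, 256-sample windows at 1/3 overlap (five windows per record),
stratified 70/30 holdout. The full-size geometry (233×868×7) is exercised
for preprocessing shape and parameter counting; full-size *training* and
the 2,880-point grid campaign are supported by the same code paths
(`run_search` with the default grid) but are cluster-scale undertakings by
nature and are not part of the default harness. Reproducing the published
Bonn-data accuracies additionally requires the external Bonn download and
stochastic GPU-scale training; they are out of scope for the test suite.

## Numerical notes and limitations

* CWT zero input → exactly zero output; |CWT| is positively homogeneous
  (tested at 1e−9 relative tolerance).
* The gmw response is evaluated in log space to avoid overflow of ω⁶⁰.
* Max-pool ties resolve to the first (row-major) maximum; odd trailing
  rows/columns are dropped by the floor pooling.
* Prediction ties (p = 0.5) resolve to the interictal class via argmax.
* float32 arithmetic throughout the network; the gradient checks run the
  engine in float64 to compare against central finite differences.
* The engine is CPU-only NumPy; no GPU, mixed precision or schedules.
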