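# Methods

`eegemotion` implements an EEG emotion-recognition pipeline for
DEAP-style recordings (32 EEG channels, 128 Hz, 63 s trials consisting of
a 3 s pre-stimulus baseline and 60 s of stimulus, rated 1–9 on valence,
arousal, dominance and liking) together with a synthetic-data generator
that makes the whole pipeline testable without the licence-gated DEAP
release.

## Pipeline

**Band decomposition.** Each channel is decomposed into Theta (4–8 Hz),
Alpha (8–14 Hz), Beta (14–31 Hz) and Gamma (31–50 Hz) with an order-30
Butterworth band-pass per band. "Order 30" is read as the order of the
analog band-pass prototype (30 pole pairs); an order-per-edge reading can
be configured through `BandDefinition.order`. The design is realised as
cascaded second-order sections — a single 60th-order polynomial is
numerically unusable in double precision — and every section is checked
for pole moduli < 1 at design time. Application is zero-phase by default
so that the phase-sensitive time-domain features (first/second
differences) are not distorted by band-dependent group delay; a causal
single-pass mode exists. Two equivalent zero-phase execution paths are
provided: forward–backward `sosfiltfilt` with reflect padding, and a
spectral path that multiplies the FFT of the reflect-padded signal by
|H(f)|² evaluated from the same section cascade. The spectral path gives
the same steady-state output (the suites assert interior agreement) and
is roughly 20× faster on dataset-scale arrays, so bulk runs use it; the
two paths are never used to validate each other's *design*, only the
application.

**Segmentation.** The 3 s baseline is discarded (it is used for nothing
downstream) and the following 60 s are cut into 10 contiguous,
non-overlapping 6 s segments (768 samples); band filtering precedes
segmentation. Every segment inherits its trial's label. A start offset
in seconds shifts the window for the robustness ablation; offsets that no
longer fit 10 × 6 s inside 63 s either raise a segmentation-overflow
error (default) or, with `truncate_tail`, drop the trailing segments —
the ablation uses the latter and reports the reduced counts. Boundaries
are computed in samples with round-half-even; all default settings give
integers.

**Features.** Six statistics per (segment, channel, band): differential
entropy, mean, mean of the first difference, mean of the second
difference, standard deviation, variance. DE uses the Gaussian closed
form ½ ln(2πe σ̂²) in nats with the biased (1/n) variance — the standard
estimator for band-limited EEG; a histogram plug-in estimator is
available for comparison. The difference means are the literal signed
sums (they telescope to (xₙ−x₁)/(n−1) and (xₙ+xₙ₋₁−x₁−x₂)/(n−2)); an
`absolute_differences` flag switches to the |·| variant used in parts of
the first-difference literature. A zero-variance segment would give
DE = −∞; it is floored at the DE of the smallest positive normal double
and logged. Features are min-max scaled to [0, 1] within one trial. The
normalization group is per (band, feature-type), pooling the trial's
channels and segments: feature types with different physical units never
share a scale, and the relative spatial topography inside one feature map
survives the scaling. Pooling everything in the trial, or normalizing per
channel, are config options (`per_trial`, `per_channel`).

**Topographic assembly.** The 32 per-channel values of one (band,
feature) pair are placed on a 9×9 grid following the 10–20 placement
(left hemisphere = odd labels in columns 0–3, midline `z` electrodes in
column 4, right hemisphere in columns 5–8; homologous pairs mirror about
the midline). Unoccupied cells are exactly zero. The grid is loaded from
a plain-text file (`layouts/deap_9x9.txt`) so a placement change is a
one-line edit. Band grids tile into one matrix — four bands 2×2 (Theta
top-left, Alpha top-right, Beta bottom-left, Gamma bottom-right; the
order is a convention and configurable), two bands side by side (9×18),
one band passes through — and the six feature matrices stack along the
depth axis: the standard configuration is an 18×18×6 tensor per segment,
the raw (unfiltered) arm a 9×9×6 one.

**Classifier.** Four convolution blocks with output channels 16, 32, 64,
128 and one fully connected layer. Each block runs parallel same-padding
convolutions of distinct kernel sizes (5×5 and 7×7 by default; any subset
of {3, 5, 7}), each producing the block's full output-channel count;
the branch outputs are concatenated along channels and fused by a 1×1
convolution back to the block width, followed by batch normalization and
ReLU. There is no pooling — spatial size is preserved end to end, which
forces same padding. Branch convolutions carry biases (their bias
gradient is annihilated by the mean subtraction of the following batch
norm, which is the expected behaviour); batch normalization sits after
the 1×1 fusion only, with momentum 0.1 and frozen statistics at
evaluation. Weights use fan-in variance scaling from a seeded generator;
the FC flatten order is channel-major.

The network is written directly in NumPy. Convolutions are computed in
the frequency domain: the zero-padded input is `rfft2`-transformed once,
outputs are per-frequency-bin contractions over input channels, and the
inverse transform is cropped back to the input size; the backward pass
applies the adjoint contractions. This is exact to float32 rounding
(asserted against a brute-force convolution and finite differences in
the test suite) and several times faster than im2col at these small
spatial sizes. 1×1 convolutions reduce to channel matmuls.

**Training and evaluation.** Adam, initial learning rate 10⁻³ annealed
by a half-cosine to 10⁻⁴ at the final epoch
(lr(e) = lr_min + ½(lr₀−lr_min)(1+cos(πe/(E−1)))); reference protocol
150 epochs, batch size 640, binary tasks via a two-logit softmax head
with cross-entropy — the binary cross-entropy of the equivalent sigmoid
on the logit difference; a literal single-logit sigmoid head is available
(`head="sigmoid"`) — and categorical cross-entropy for the four-class
task. Evaluation is k-fold cross-validation (k = 10) with folds drawn at
random over **all segments pooled across subjects and trials**, each fold
trained from a fresh initialization, accuracy measured once on the
held-out fold after the final epoch, and the mean of fold accuracies
reported. Note that segment-level folding places segments of the same
trial on both sides of the split, so these accuracies are optimistic with
respect to a truly unseen subject or trial; `group_by="trial"` or
`"subject"` provides leakage-free folding for honest benchmarking. The
default replicates the reference protocol deliberately.

**Labels.** Ratings are binarized at 5 with *high* meaning rating > 5
(a rating exactly at the split point is low; the threshold and the
convention are configurable). The four-class task is the cross product,
ordered HAHV, HALV, LAHV, LALV (indices 0–3).

## Synthetic data

The generator emulates exactly the statistical structure the pipeline
exploits, and nothing else:

- **Band content**: per band, noise synthesized by FFT-masking white
  noise to the band (brick-wall edges, unit RMS). This synthesis is
  deliberately independent of the Butterworth filter bank so generator
  and filter bank never validate each other circularly.
- **Spatial correlation**: each electrode mixes a shared regional source
  with private noise, weight `spatial_smoothness` s ∈ [0, 1]
  (default 0.8). The regional sources are nine anchor processes on a 3×3
  lattice over the scalp grid, combined per electrode with Gaussian
  weights of scale 2 grid cells, so correlation decays smoothly with
  electrode distance — grid-adjacent electrodes end up strongly
  correlated, distant ones weakly.
- **Background**: independent 1/f^α noise per electrode (α = 1 by
  default, unit RMS against band amplitudes of 1).
- **Class signal**: the arousal class scales the Beta amplitude and the
  valence class the Gamma amplitude on a designated electrode group
  (frontal F3, F4, Fz, FC1, FC2 by default) by 1 + effect for the high
  class and 1 − 0.5·effect for the low class. `effect_size = 0` yields
  label-independent signals; the default study condition is 1.0 and the
  recovery experiments use 1.5. Coding the two tasks in different bands
  keeps both binary tasks and the four-class task recoverable.
- **Ratings**: drawn uniformly from (5, 9] for an injected high class and
  [1, 5) for a low one (never exactly 5), balanced within each subject;
  dominance and liking are uninformative uniforms.
- **Reproducibility**: one global seed spawns per-subject and per-trial
  seed sequences, so any subject or trial is bit-reproducible in
  isolation. A small per-trial amplitude jitter (5%) gives trials
  individual character.

Not modelled: event-related potentials, blinks, drift, electrode
impedance changes, inter-subject variability of any structured kind.
Passing tests therefore show that the pipeline recovers the statistical
structure it assumes — class-coded high-band power over a coherent
electrode group — not that it attains any particular accuracy on real
recordings.

## Problem sizes and numerical choices

Training-based checks run at desk scale, chosen so the full suite
completes comfortably on one CPU: the label-recovery experiment uses 4
synthetic subjects (1,600 segments), the reference architecture with
reduced block widths (4, 4, 8, 8), 20 epochs, batch 64, 10-fold CV; the
shift-robustness check uses 2 subjects, 10 epochs, 5 folds at offsets
{0, 1, 2} s; `scripts/acceptance.py` uses 2 subjects, 15 epochs, 5
folds. Widths are capacity dials — the block structure, fusion, schedule
and folding are the reference ones throughout. The full-size pipeline
(32 × 40 trials → 12,800 tensors) is exercised end to end for the
cardinality check, streaming one subject at a time.

Other numerics: filter response comparisons use the steady-state interior
of test signals (1,000-sample margins); `sosfiltfilt` padding is
`min(n−1, 6·order+1)` samples; spectral filtering reflect-pads by 512
samples and rounds the FFT length up to a fast size; degenerate
normalization groups map to 0 with a warning; fold sizes differ by at
most one when k does not divide n; per-epoch shuffling is seeded by
(seed, fold, epoch) so runs are bit-reproducible on one machine.

## Known limitations

- Segment-level CV leaks trial identity; reported accuracies on
  correlated data are upper bounds (see above for leakage-free options).
- The Gaussian DE closed form is exact only for Gaussian segments; for
  strongly non-Gaussian signals the histogram estimator will disagree.
- The spectral filter path differs from `sosfiltfilt` near the first and
  last ~1 s of a trial (different edge handling); segment features start
  3 s into the recording, where the two agree.
- Batch norm statistics with batch 64 are noisy for very small widths;
  evaluation uses running averages accumulated over all training steps.
- The generator's balanced classes make chance level exactly 50% / 25%;
  real rating distributions are imbalanced and would need stratified
  folding for calibrated baselines.
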