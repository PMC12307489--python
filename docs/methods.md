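# Methods

## Problem and model

The package classifies 4-class motor-imagery EEG trials (left hand,
right hand, feet, tongue) from 22-channel recordings sampled at 250 Hz,
the layout of BCI Competition IV dataset 2a.  Imagining a movement
suppresses the band power of ongoing mu (8–12 Hz) and beta (18–26 Hz)
rhythms over class-specific sensorimotor electrodes (event-related
desynchronization, ERD); the classifier's task is to decode *which*
electrodes lose band power in a 3-second post-cue window.

HA-FuseNet decodes trials with two parallel branches fused along the
feature-map (depth) dimension:

* **DIS-Net** (convolutional): stem temporal convolution on the trial
  viewed as a 1 × C × T map → inverted bottleneck (1×1 expand, GELU,
  depthwise temporal convolution, 1×1 project) → two multi-scale dense
  blocks (parallel temporal convolutions with different kernel lengths,
  depth-concatenated with the block input) each followed by svSE
  attention → axial depthwise-separable spatial convolution collapsing
  the electrode axis → svSE → temporal pooling → linear head.  Every
  stage preserves T; only the final pooling reduces temporal
  resolution.
* **LS-Net** (recurrent): stacked LSTM layers over the raw C × T trial;
  after each layer the H × T hidden-state map passes through SCoT
  global attention with H treated as the channel axis.
* **Fusion**: the recurrent output returns to map form through the R2C
  per-time-step linear projection and is depth-concatenated with
  DIS-Net's pre-pool features; a depthwise separable convolution mixes
  the fused map, then pooling, flattening and a linear head produce the
  4-class scores.  C2R (the reverse projection) optionally feeds a
  DIS-Net intermediate map into LS-Net instead of the raw trial
  (`lsnet.input_mode: c2r`); raw input is the default.

### svSE attention

Three branches weight a D × C × T feature map:

* channel excitation `att_c` (D × 1 × 1): global max pooling over
  (C, T), a reduce–expand MLP, softmax over depth.  The MLP is
  weight-tied across depth maps (a scalar → D/r → scalar network
  applied to every pooled value), so equally salient maps receive equal
  weights and the depth softmax alone distributes attention; a
  cross-map MLP would assign unequal weights even to identical maps.
* variance branch `att_v` (1 × C × T): the per-position depth mean and
  population depth variance are stacked and mixed by a 1×1 convolution,
  then softmax-normalized over the C·T positions — variance marks where
  the non-stationary signal is active.
* axial branch `att_s` (1 × C × T): a depth-compressed map is pooled
  along time (average + max, fused 1×1) into a per-electrode factor and
  filtered along the electrode axis (full-span C × 1 kernel) into a
  per-sample factor; each factor is softmax-normalized along its own
  axis and their outer (Kronecker) product restores the C × T map.
  The product of two distributions is itself a distribution over the
  C·T positions and is rank-1 by construction.

Gating: the weighted output is `(att_v ⊕ att_s) ⊗ X  ⊕  att_c ⊗ X`.
Because the softmax maps are distributions, using them directly as
gates scales activations by ~1/(C·T) and ~1/D and starves every
downstream layer of gradient signal (measured: the desk-scale model
then sits at chance for its whole training budget); rescaling them to
unit mean instead explodes activations whenever the softmax
concentrates (measured: activation standard deviation above 10³ after
three svSE stages).  The gates are therefore the softmax maps
normalized by their per-sample maximum: peak weight 1, range (0, 1] —
the range of the sigmoid that softmax replaces — with the softmax's
relative weighting intact.  The normalized maps themselves are what
the weight accessors return and what the weight-sum and rank-1
properties are asserted on.  A `residual` flag optionally adds an
identity copy of X (off by default; the composition equation sums only
the two gated terms).

### SCoT attention

Stage 1 adapts the Non-local block to the electrode axis: each channel
is a token described by its time-averaged depth vector, so the
similarity matrix is C × C; query/key/value are per-token linear maps
at ⌈D/2⌉ depth (floor 1), similarities are softmax-normalized row-wise,
and the re-expanded output adds back residually (broadcast over time).
Pooling over time before the similarity keeps the stage cheap and
well-conditioned for spatial data with weak local correlation; a
time-resolved token mode was considered and rejected for cost.
Stage 2 adapts the Contextual-Transformer block to the time axis: the
static-context key K is a same-padded 1×3 temporal convolution, the
query is the input itself, the value a 1×1 projection; the attention
map A comes from two consecutive 1×1 convolutions (GELU between, middle
depth ⌊D/2⌋, floor 1) on the depth-concatenation of K and the query,
and the dynamic context is the local sum of A ⊗ V over the 3-sample
kernel footprint.  Output = static ⊕ dynamic.  Two axis-wise stages
cost far less than one joint (C·T) × (C·T) attention; the package
asserts the multiply–accumulate inequality explicitly.

### SG lightweight convolution

`SGModule(d_in, d_out, ratio, kernel)` computes `round(d_out · ratio)`
maps with a standard temporal convolution and derives the remaining
maps from them with a cheap path: depthwise 1×k convolution → batch
normalization → 1×1 pointwise to the remaining depth → batch
normalization → GELU; the two groups are depth-concatenated so output
depth is exactly `d_out` for every ratio in (0, 1] (ratio 1 degenerates
to the standard convolution).  `model.variant: sg` swaps SG blocks in
for the dense-block branch convolutions.  Fractional map counts round
with a floor of one map per path.

## Training and evaluation

Categorical cross-entropy on the raw class scores (log-sum-exp form),
Adam with learning rate 1e-3, weight decay 5e-3 (added to the
gradient), batch size 32, a fixed epoch count, no validation split or
early stopping by default (a `val_fraction` option exists).  The
benchmark recipe is 300 epochs; desk-scale runs use 40.  One master
seed fans out to parameter initialization, batch order and dropout.

Metrics: per-subject accuracy; Cohen's kappa from the confusion matrix,
`(P0 − Pe)/(1 − Pe)` with `Pe = Σ x_i P_i / N²`; and the across-subject
stability measure SD, the sample standard deviation (÷(N−1)) of
per-subject accuracies.  Within-subject protocol: one model per
subject, trained on its training session (T) and tested on its
evaluation session (E).  Cross-subject protocol (leave-one-subject-
out): for subject i the training pool is the union of all other
subjects' T sessions; the test set is subject i's E session.

## Preprocessing

EOG channels are excluded on read; NaN run gaps are imputed with the
channel mean (idempotent); epochs span [cue + 1 s, cue + 4 s) with
0-based, half-open indexing, so an epoch is exactly 3 s × fs samples;
events whose window overruns the recording are dropped with a warning.
Z-scoring uses the population σ convention, per trial and channel over
time by default (scope configurable to per-channel-over-session);
groups with spread below ε = 1e-8 map to zeros.  Min-max scaling to
[0, 1] is available but not the default: it is sensitive to transient
artifacts.  No band-pass filtering and no artifact correction beyond
imputation — broad-band structure is part of the signal.  Evaluation
session statistics are computed on the session itself (self-contained
per-trial scope); freezing training-session statistics is the
configurable alternative.

## Synthetic data

The generator emulates cue-based motor-imagery sessions: a 1/f-shaped
background (per-channel RMS `noise_sd`, default 1 µV), plus ongoing
narrowband mu/beta oscillations (RMS `rhythm_amplitude`, default 2 µV)
on class-specific electrodes.  Oscillations are stochastic narrowband
noise (Gaussian spectral envelope), not fixed sinusoids: ongoing
rhythms decorrelate in phase on the ~1/bandwidth timescale, so no
waveform template repeats across trials and band power per electrode is
the only stable class cue — exactly the ERD feature.  (An earlier
sum-of-sinusoids draft let a high-capacity model memorize
session-specific phase templates instead of learning band power.)
During each trial of the matching class the oscillation amplitude is
multiplied by the attenuation factor over [cue + 0.5 s, cue + 4 s],
ramped linearly over 0.5 s — a gradual-onset ERD analogue.  Attenuation
1.0 yields signal-free null data.  Per-subject variability is a random
log-normal channel gain (`subject_shift_sd`, default 0.2).  Defaults
mirror the target dataset (22 channels, 250 Hz, 4 balanced classes);
determinism is per (seed, subject, session).

What the generator does *not* model: volume-conducted scalp
topographies, EOG/EMG artifacts, inter-electrode correlation structure,
non-stationary drift, or realistic cross-subject frequency shifts.
Passing the learning checks therefore shows the pipeline can discover
spatially specific band-power modulation end-to-end — not that it
matches published accuracies on real recordings.

## Desk-scale study conditions

The benchmark configuration (250 Hz, nine subjects, 300 epochs,
GPU-scale widths) is far beyond a single-CPU budget.  The package's own
desk-scale conditions (`hafusenet.experiments`) are: synthetic sessions
at 50 Hz (mu 10 Hz and beta 18 Hz sit below the 25 Hz Nyquist), 22
channels, 9 subjects × 80 trials (20 per class), ERD attenuation 0.3
with background noise 0.5 µV for the separable condition and
attenuation 1.0 for the null condition; a scaled-down model (~36k
parameters: depths 4, branch kernels 5/9 ≈ 100/180 ms, LSTM hidden 48
with 5× input time pooling) trained 40 epochs at batch 32.  The null
check trains 10 epochs — chance-level data cannot improve with longer
training, and the shorter budget keeps the whole suite CPU-friendly.
Training on the pooled T sessions and testing on the pooled E sessions
measures held-out accuracy.

Three desk-scale configuration choices matter for learnability within
the 40-epoch budget, all exposed as ordinary configuration:

* **Normalization scope.** The desk experiments z-score per channel
  over the whole session (`channel_session`).  Per-trial scoping — the
  package default elsewhere — rescales every trial and channel to unit
  variance, which deletes the ERD amplitude cue itself and leaves only
  a subtle spectral-shape signal; a linear probe on log channel
  variances separates the session-scoped data perfectly, so the cue
  survives that scope.  Session-level standardization is also the norm
  in EEG deep-learning pipelines for exactly this reason.
* **Global average pooling** (`pool_size` = epoch length).  Band power
  is stationary across the analysis window; time-resolved pooled
  features mainly offered a trial-memorization channel (removing them
  closed a large train/test gap).
* **svSE residual** (`svse_residual: true`).  Magnitude-driven
  attention systematically down-weights exactly the low-power
  (desynchronized) channels that carry the class label; without an
  identity path the CNN branch never recovers the band-power code at
  this scale (measured: 29% vs 100% held-out accuracy with the
  residual).  The residual form is one of the two documented readings
  of the module diagram.

## Numerical core

No array autodiff framework ships in the dependency set, so the models
run on a small reverse-mode autodiff engine (`hafusenet.nn`) over
float32 numpy arrays: broadcasting arithmetic, matmul, the
nonlinearities (exact erf-based GELU), axis reductions, shape surgery,
concatenation, and fused kernels with hand-written backward passes for
temporal/depthwise/channel-collapse convolutions (im2col + BLAS matmul
with an offset-loop fallback above a memory budget) and the LSTM (full
backpropagation through time).  All kernels are verified against
central finite differences in the test suite.  Softmax subtracts a
detached max; the z-score and variance guards use ε = 1e-8; batch
normalization (used by the SG cheap path; optional elsewhere and off by
default) uses ε = 1e-5 and momentum 0.1.  Adam follows the standard
bias-corrected update with L2 weight decay added to the gradient.

## Known limitations

* Benchmark-scale accuracies on the real dataset are out of reach at
  desk scale by design; no claim is made about real-data accuracy.
* The R2C/C2R adapters and several wiring details (svSE softmax axes,
  SCoT residual, CoT aggregation) are under-determined by the source
  architecture description; the choices above are documented and
  config-switchable where reasonable.
* Batch normalization outside the SG module is available
  (`disnet.use_batchnorm`) but off by default: with unit-variance
  normalized activations the svSE softmax gates saturate the training
  plateau at the desk scale.
* Training at 50 Hz shrinks the beta band's headroom; kernels were
  resized accordingly (the 100 ms anchor is preserved: 5 samples at
  50 Hz vs 25 at 250 Hz).
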