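# Methods

This note records the modeling choices in `eegmixer`, their rationale,
and what the bundled synthetic data can and cannot demonstrate.

## Signal model and preprocessing

Inputs are continuous 19-channel recordings in microvolts on the
International 10-20 montage, sampled at 128 Hz. Montage validation is
case-insensitive, reorders channels to a fixed canonical order, rejects
missing or duplicated electrodes, and drops the earlobe references A1/A2
from the data tensor (they are references, not scalp channels).

**Band-pass filter.** A sixth-order Butterworth band-pass with 4 and
45 Hz cutoffs, realized digitally via the bilinear transform with
frequency prewarping and factored into cascaded second-order sections
(SOS). A direct high-order polynomial realization is numerically fragile
at fs = 128 Hz with a 45 Hz cutoff close to Nyquist; SOS is the standard
stable form. The half-power (-3 dB) points of the single-pass design
response sit at the requested cutoffs to better than 1%.

Filtering is applied **zero-phase** (forward-backward over the
sections, `sosfiltfilt`). Zero-phase filtering is standard EEG practice
because phase distortion shifts features across the epoch boundary; the
cost is that the effective magnitude response is squared (12th-order
roll-off). All half-power statements refer to the single-pass design
response. A causal single-pass mode is deliberately not offered — epochs
are consumed whole, so there is no latency constraint.

**Epoching.** Non-overlapping contiguous 4-s windows (N = 512 samples),
stride = N, trailing remainder dropped. Epoch counts therefore satisfy
`n_epochs * N + dropped = T` exactly.

**Standardization.** Per-channel z-scoring with mean/sd estimated from
training data only and reused on validation/test data (sd floored at
1e-8 for degenerate channels). Raw microvolt amplitudes (tens of µV)
destabilize Adam at lr 1e-4; z-scoring is the plumbing that makes the
stated learning rate workable and is on by default in the pipeline.

## Network

The classifier is a 1-D ConvMixer with channel attention. Defaults:

| parameter        | default | meaning                                      |
|------------------|---------|----------------------------------------------|
| `patch_size` p   | 4       | embedding stride; tokens = L/p = 128 per epoch |
| `hidden_dim` C_p | 64      | token channel width                          |
| `depth`          | 8       | number of mixer blocks                       |
| `dw_kernel`      | 9       | depthwise (temporal) kernel, odd, same-padded |
| `eca_gamma` γ    | 2       | ECA kernel-size rule parameter               |
| head             | single logit + sigmoid | paired with BCE loss          |

Only the depth is fixed by the method description; patch size, hidden
width, and the depthwise kernel follow the original ConvMixer's published
choices, transplanted to the 1-D EEG setting (channels = electrodes,
positions = time). All are configurable.

**Block structure.** `X' = X + Attn(PW(GELU(DW(X))))` — the residual
wraps the whole block. The original ConvMixer instead wraps only the
depthwise stage and adds per-conv BatchNorm; a `residual="depthwise"`
flag restores the original placement, and no intra-block normalization is
used (training is stable without it at the stated learning rate on
z-scored inputs, and the leaner block keeps the in-package autodiff
engine minimal).

**ECA.** Positions are average-pooled to a per-channel descriptor; a
single 1-D kernel slides across the *channel axis* with circular
indexing (wrap-around, selectable zero-padding), followed by a sigmoid
gate. The kernel size adapts to the channel count. Two rules are
implemented:

* `eca-log2` (default): `k = |log2(C)/γ + 1/γ|`, truncated, bumped to
  odd — the original ECA recipe; with C_p = 64, γ = 2 it gives k = 3.
* `linear`: `k = round(C/γ) + 1` — a linear-in-C variant; with small γ it
  yields kernels wider than the channel descriptor, which is why it is
  not the default.

Both results are raised to the nearest odd integer ≥ 3 so the circular
neighborhood is symmetric about the target channel. The attention gates
are strictly inside (0, 1), so the ECA stage never amplifies a channel.

**Attention variants.** For ablations, SEA (squeeze-and-excite:
GAP → bottleneck MLP with reduction r = 16 → sigmoid), CBA (CBAM-style
channel attention from shared-MLP over avg- and max-pooled descriptors,
then spatial attention from a k = 7 convolution over stacked channel
avg/max maps), and NLA (embedded-Gaussian non-local block over positions,
row-stochastic attention matrix, residual output projection) are drop-in
replacements with the same shape contract. The method description names
these variants without formulas; the canonical literature definitions
are used with their canonical defaults.

**Initialization.** Convolution and embedding weights: uniform fan-in
(`U(±1/sqrt(fan_in))`) from a fixed seed — bitwise-reproducible. The
classification head (weights and bias) starts at zero, so the untrained
network outputs zero logits and training begins exactly at the
no-information BCE of ln 2 ≈ 0.693 on balanced data. Zero-initializing
the final layer is a common stabilization; gradients flow because the
pre-head features are nonzero.

**Autodiff.** The forward pass, gradients, and Adam are implemented in
NumPy in `eegmixer.autodiff` (reverse-mode tape over a small op set:
grouped/strided 1-D convolution, circular padding, GELU/sigmoid/softmax,
reductions, batched matmul, stable BCE/cross-entropy). Every op's
backward pass is tested against central-difference numerical gradients.
Computation is float64 throughout; at the package's problem sizes this
costs little and removes a class of tolerance questions.

## Training and evaluation protocol

* Optimizer: Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8), lr 1e-4, batch 64,
  30 cycles by default; per-cycle reshuffling of the training epochs with
  a seeded generator.
* Loss: BCE on the single logit (a two-logit softmax head with
  cross-entropy is selectable).
* Checkpointing: the best-validation-loss parameters are retained.
* Splits: label-stratified selection of ~20% of *subjects* for testing
  (at least one per class); the remaining subjects' epochs are shuffled
  70/30 into train/validation. The test boundary is subject-disjoint —
  epochs of one subject never straddle it — which is the only reading of
  the protocol that avoids identity leakage. Train and validation share
  subjects by construction (the 70/30 split is applied to the training
  *data*, i.e. at the epoch level).
* Cross-validation: subjects are partitioned into label-stratified
  folds; each fold is tested exactly once by a freshly initialized and
  freshly standardized model. Fold-level subject disjointness is asserted
  at run time.
* Decision threshold 0.5 on the positive-class probability; ROC/AUC via
  a threshold sweep over unique scores with trapezoidal integration
  (equal to the normalized Mann-Whitney U statistic, which the tests
  assert independently).
* Degenerate metric conventions: precision = 0 when nothing is predicted
  positive; F1 = 0 when its denominator is zero.

## Synthetic cohorts

The generator emulates the statistical structure the classifier
exploits, not EEG physiology. Per channel, a recording is a sum of
band-limited random-phase oscillations — theta 4-8 Hz, alpha 8-12 Hz,
beta 13-30 Hz, with TD-class RMS amplitudes 10/8/6 µV — plus 1/f-power
pink noise at 5 µV RMS. Those amplitudes put the class contrast well
above the noise floor while keeping single-epoch band-power estimates
noisy, which is the qualitative regime of the real biomarker. The
ADHD-like class multiplies theta amplitude by 1.5 and beta by 0.67 (the
reported direction of the pediatric ADHD band-power abnormality), and
each subject draws one lognormal amplitude multiplier per band
(σ = 0.1), shared across channels, so subjects are coherently high- or
low-power. Per-subject seeds derive from the master seed; generation is
bitwise reproducible.

Because band power scales as amplitude squared, the class power ratio in
the theta band estimates `theta_factor²`; the tests recover the factor
to within 15% from 20 subjects per class, and to a few percent at the
80-subject scale.

**What passing tests do not show:** the generator has no eye blinks, EMG,
line noise, volume conduction, non-stationarity, or inter-channel
covariance structure; classes differ only in band power. High accuracy
here demonstrates that the pipeline is leak-free and the model can learn
spectral-power contrasts end to end — not that comparable accuracy is
achievable on clinical recordings. Reproducing published clinical
numbers requires the corresponding public dataset (EDF ingest is
supported via `eegmixer[edf]`).

## Problem sizes in bundled checks

The self-contained end-to-end check trains a reduced network (depth 4,
hidden 32, 10 cycles) on a 40+40-subject cohort of 60-s recordings
(1200 epochs), chosen as the smallest cohort at which subject-level
variability is well represented; it reaches ≥ 0.90 held-out epoch
accuracy in well under a minute on one CPU. The full-size default
(depth 8, hidden 64, 30 cycles) is what the CLI uses unless configured
otherwise.

## Known limitations

* No artifact rejection, re-referencing, or resampling — recordings are
  assumed clean and uniformly sampled at one rate.
* The in-package autodiff engine is single-threaded NumPy; it is sized
  for research-scale experiments, not large-scale training.
* t-SNE diagnostics use PCA pre-reduction to 50 dimensions, perplexity
  30, 1000 iterations (all configurable); embeddings are seeded and
  deterministic but, as always with t-SNE, not comparable across runs
  with different seeds.
* The confusion-matrix positive class is fixed to ADHD-like (label 1);
  unlabeled recordings carry label -1 and are excluded from metrics.
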