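# Methods

## Model

SEF-UNet is a four-stage U-shaped encoder–decoder for 2-D axial CT slices.

**Encoder.** Stage *i* (i = 1..4) is a strided downsampling convolution
followed by *L<sub>i</sub>* SEFormer blocks at constant channel width
*C<sub>i</sub>*. A SEFormer block is the MetaFormer residual pair — channel
LayerNorm → token mixer → residual, then channel LayerNorm → position-wise
two-layer MLP → residual — with the token mixer instantiated as an
SE-gated depthwise-separable convolution: a 1×1 expansion to
⌊e·C⌋ channels, activation, a per-channel k×k depthwise convolution
(stride 1, same padding), squeeze-and-excitation gating on the expanded
channels (global average pool → bias-free FC to ⌊eC/r⌋ → ReLU → bias-free
FC back → sigmoid → channel-wise rescale), and a 1×1 projection back to C.
Token mixer and MLP both preserve (C, H, W) exactly, so the residuals are
plain additions.

**Downsampling.** The stem is a 7×7 convolution with stride 4 and padding 2;
stages 2–4 downsample with 3×3 / stride 2 / padding 1. Stage resolutions are
therefore 1/4, 1/8, 1/16 and 1/32 of the input, which is required to be a
multiple of 32. The downsampling convolutions carry biases and no
normalization layer.

**Decoder.** Four dCUP blocks. Each bilinearly upsamples ×2
(half-pixel-centred interpolation, align-corners false — documented so runs
are bit-reproducible), concatenates the matching encoder skip (blocks 1–3;
there are only three skips, so block 4 runs without fusion), applies a 3×3
convolution to the block's output width (bias-free, since batch
normalization follows), BatchNorm, ReLU, and — in the `dcup` variant — a
trailing 3×3 depthwise convolution. The `cup` variant omits the depthwise
convolution; `none` bypasses the decoder entirely and classifies the
bottleneck directly. Four ×2 steps from 1/32 reach 1/2 resolution, so the
segmentation head (1×1 classifier) performs the final bilinear ×2 to input
size; decoder plus head jointly restore the original resolution.

**Classes.** 9 = 8 organs + background. Foreground order is fixed:
spleen, right kidney, left kidney, gallbladder, liver, stomach, aorta,
pancreas (labels 1–8, background 0).

## Calibrated ratios and the parameter budget

The stage layout (depths [3, 3, 9, 3], dims [64, 128, 320, 512], decoder
channels [256, 128, 64, 16]) pins most of the architecture, but the mixer
expansion *e*, SE reduction *r*, MLP ratio *m*, and the encoder depthwise
kernel are free. They were calibrated once, by exhaustive grid search over
plausible values, to the published 24.65 M total:

  e = 1.75, r = 4, m = 3.125, encoder depthwise kernel 5×5,
  SE FC layers bias-free, decoder conv-before-BN bias-free,

giving 24,649,193 learnable scalars (24.65 M at two decimals), counting all
weights, biases and normalization parameters including the segmentation
head. These are configuration knobs, not constants.

**Known inconsistency.** The multiply–accumulate count of the calibrated
model at 224×224 is 4.36 G (convolutions and FC layers, one MAC per
FLOP-unit) — a ~35× reduction versus the 154.03 G of UNet3+, not the
published 5.16 G / 29.8×. The two published figures cannot both hold for
this architecture family: matching 24.65 M parameters bounds the per-block
C²-coefficient of parameters to ≈ 11.3, while 5.16 G would need a per-block
C²·HW MAC coefficient of ≈ 12.5 — yet the MAC coefficient (2e + 2m) can
never exceed the parameter coefficient (2e + 2e²/r + 2m). We therefore
treat the parameter count as the binding constraint and report the MAC
count our faithful counter produces; the corresponding acceptance test is
expected to fail and documents the discrepancy.

## Loss

`L = (L_CE + L_Dice) / 2` on softmax probabilities. CE is averaged over
pixels, with probabilities floored at 1e−12 inside the log so a zero
probability at a true label is a large finite penalty. The soft Dice
complement is accumulated over all pixels of the batch per class
(batch-Dice — more stable for small structures than per-image Dice, which
the source formulation leaves unspecified), ε = 1e−5 in numerator and
denominator, averaged over classes with background included by default
(toggle provided).

## Metrics

DSC = 2|A∩B|/(|A|+|B|) per organ, with both-masks-empty → 1.0 and exactly
one empty → 0.0 (the underlying convention is undefined; these choices are
documented and tested). HD95 is computed in 3-D on the stacked prediction:
boundary voxels are mask voxels with a 6-connected background neighbour,
voxel indices are scaled by the (mm) spacing, distances from each boundary
to the other are pooled into one set, and the 95th percentile of the pooled
set is reported. One-sided-empty cases return the volume diagonal in mm as
a sentinel. Cohort summaries average per-case means over the foreground
classes only and print DSC as percent.

## Preprocessing, augmentation, inference

HU values are truncated to [−125, 275] and mapped linearly to [0, 1]
(idempotent once applied, given the updated window). Volumes are handled
slice-major (D, H, W), axial = first axis. Training slices are resized to
the model resolution with bilinear interpolation (labels nearest-neighbour,
so no new label values can appear). Augmentation: with p = 0.5 a random
flip or 90°-multiple rotation, otherwise with p = 0.5 a rotation uniform in
[−20°, 20°] (image bilinear, label nearest, identical transform for both);
the exact probabilities and range follow common practice for this benchmark
family and are configurable. Inference is strictly slice-wise: normalize,
resize, classify, argmax, nearest-neighbour resize of the *label map* back
to native slice size (resizing labels rather than logits avoids class
mixing), stack in order.

## Training

SGD with momentum 0.9, weight decay 1e−4 added to the gradient, constant
learning rate 0.01, batch 24, 150 epochs — the published recipe — with
seeded shuffling and per-epoch mean-loss logging. `max_iterations` caps
total steps for smoke runs and overfitting studies. Weights are initialized
truncated-normal (σ = 0.02, cut at 2σ), biases zero, norm scales one, from
a single seeded generator, so runs are exactly reproducible on the same
machine settings. Checkpoints are flat name→array maps; names follow the
module tree and are stable across refactors.

## Numerical substrate

The network runs on a small reverse-mode autodiff over float32 numpy
arrays. Convolutions use im2col + BLAS matmul forward; the input gradient
is computed as a transposed convolution (stride-dilated gradient, full
padding, flipped kernels) through the same im2col path. Bilinear resizing
is separable and implemented as two precomputed 1-D interpolation matrices,
which makes its adjoint exact. Layer/batch normalization are composed from
differentiable primitives. All kernels are gradient-checked against central
finite differences in the test-suite.

## Synthetic phantoms

The phantom generator emulates what the pipeline needs from abdominal CT —
a soft-tissue body on air background, 8 distinct-intensity structures
(means spanning −150…320 HU so the display window clips at both ends),
Gaussian HU noise (σ = 10), anisotropic spacing (3, 1, 1) mm, and two organ
pairs sharing a boundary to mimic organ occlusion. Organs are single
ellipsoids painted in a fixed order (snapped adjacency partners last), with
later paint winning at overlaps; everything is a pure function of the seed.
The phantoms deliberately do **not** reproduce real anatomy, organ shape
priors, partial-volume effects or scanner noise spectra, so tests passing
on phantoms demonstrate pipeline correctness and trainability, not
clinical-grade accuracy on patient data.

## Problem sizes used in the test-suite

Unit tests exercise operators on ≤ (4-channel, 7×7) tensors against loop
oracles and the default-width encoder once at 224×224. The
overfit-recovery check trains a reduced model (dims [16, 32, 64, 128],
depths [1, 1, 2, 1], decoder [64, 32, 16, 16], 96×96 input) on the 24
slices of one phantom case for 1500 iterations at batch 4 with learning
rate 0.03 (the larger rate suits the small batch and model; the published
0.01/batch-24 recipe is kept as the training default), then requires mean
foreground DSC > 0.90 on that same case via the full 3-D inference and
evaluation path. These sizes are the package's own choice of a
desk-scale experiment with an unambiguous expected outcome.

## Limitations

- No pretrained encoder weights are bundled; the published benchmark
  accuracy additionally relies on ImageNet21k pretraining and the
  restricted 30-scan dataset, so it is not reproduced here.
- 2-D slice-wise inference has no through-plane context; HD95 on thick
  slices inherits the usual staircase artifacts.
- No test-time augmentation, sliding windows, ensembling or learning-rate
  schedules (an optional polynomial decay hook exists but is off).
- CPU-only numpy execution: fine for the reduced models in the tests,
  slow at full 224×224 width.
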