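# Methods

## The model

`daunet` implements a residual U-Net for binary segmentation of breast
tumors in grayscale ultrasound images. The network maps a 128 × 128 × 1
image in [0, 1] to a per-pixel foreground probability of the same shape.

**Encoder.** Each stage is a residual block — two 3 × 3 convolution /
batch-norm / ReLU stages plus a shortcut (a 1 × 1 projection when the
channel count changes) summed *without* a trailing activation — followed by
a 2 × 2 stride-2 convolution (with BN/ReLU) that halves resolution and
doubles channels. Defaults: 4 stages at 32/64/128/256 channels with a
512-channel bottleneck residual block. Depth and width are configurable;
the test and acceptance runs use depth 3, base 8 so that full pipelines run
in seconds-to-minutes on one CPU.

**Attention-gated skips.** Each encoder skip feature may pass through one
of three shape-preserving attention blocks before fusion with the decoder:

* *Channel attention*: a gate σ(mlp(gap(F)) + mlp(gmp(F))) per channel,
  where gap/gmp are global average/max pooling and the MLP is a shared
  bottleneck of two dense layers C → max(1, C/8) → C. The bottleneck is
  linear by default; a ReLU between the layers is available as an option
  (`mlp_activation="relu"`). The linear default reads the gate as exactly
  two dense layers and avoids an artifact of narrow models: with one or
  two hidden ReLU units, a unit that is dead at initialization receives
  zero gradient forever and can never recover.
* *Spatial attention*: channel-wise average and max maps, each passed
  through a per-position 1 → 1 dense layer (on by default, switchable off),
  concatenated and convolved with a 7 × 7 kernel of dilation 4 under
  'same' padding, then sigmoid-squashed to a per-pixel gate.
* *Position attention (PAM)*: 1 × 1 convolutions produce query/key/value
  grids B, Z, D (all at C channels by default; an optional channel
  reduction for B and Z exists). With N = H·W positions, the affinity
  S[j, i] = softmax_i(B_i · Z_j) re-weights D, and the output is
  α · (S D) + F with the scalar α a learnable parameter initialized to
  exactly 0 — so the block starts as the identity and training moves it
  away from zero. The softmax subtracts the row maximum before
  exponentiation.
* *PCBAM*: the element-wise sum PAM(F) + CBAM(F) of the two branches
  applied to the same input (CBAM = channel gate then spatial gate,
  both multiplicative).

The N × N affinity is evaluated in row blocks (~64 MB each) and recomputed
during the backward pass instead of being stored: at a 128 × 128 skip,
N = 16384 and a dense float32 affinity alone is ~1 GiB, which would
otherwise dominate memory.

**Bottleneck attention (SWA block).** Three learnable C × C matrices
project every position to query/key/value grids; the three grids are
concatenated along channels and fused by a 1 × 1 convolution (3C → C),
and the result is added residually to the input. Despite the name, the
block contains no window partitioning, shifting, or softmax(qkᵀ): the
fusion is purely convolutional. A genuine windowed softmax attention
(non-overlapping windows, scaled dot product) is available behind
`swa_window_softmax=True` for experimentation, default off. Placement is
at the bottleneck by default (`swa_placement="bottleneck"`); `"decoder"`
(after the first decoder stage) is selectable.

**Decoder.** 2 × 2 stride-2 transposed convolutions double resolution;
the upsampled feature is concatenated with the attention-gated skip
(channel concatenation by default; additive fusion is selectable) and
refined by a residual block. The head is a 1 × 1 convolution with a
sigmoid; probabilities are numerically confined to [1e-7, 1 − 1e-7] so the
open-interval output contract holds in float32 even for saturating logits
(where the sigmoid gradient is zero regardless).

**Ablation variants.** `variant_config("i")` … `("v")` build: (i) the plain
residual U-Net, (ii) PAM-gated skips, (iii) CBAM-gated skips, (iv)
PCBAM-gated skips, (v) PCBAM + the bottleneck SWA block.

## Losses

Training minimizes Dice + BCE + Focal (unit weights by default, each
component re-weightable, so single losses and pairs are selectable):

* Dice loss `1 − (2·TP + ε) / (2·TP + FP + FN + ε)` on soft counts
  (TP = Σ y·p …), ε = 1e-6 in numerator and denominator so an empty mask
  predicted empty scores 0 rather than 0/0.
* BCE: mean of −[y log p + (1−y) log(1−p)], probabilities clipped to
  [1e-7, 1 − 1e-7].
* Focal: mean of −α (1 − p_t)^γ log(p_t) with p_t = p where y = 1 and
  1 − p where y = 0; α = 0.25, γ = 2, the canonical defaults, both
  configurable. At γ = 0, α = 1 it reduces to BCE.
  The literal one-sided form −α(1−p)^γ log(p), which ignores background
  pixels and cannot train a segmenter by itself, is kept behind
  `literal_focal=True` for comparison only.

All reductions are per-pixel means over everything in the batch.

## Metrics

Hard metrics from thresholded predictions (threshold 0.5, ties to
foreground): accuracy, precision, recall, IoU, Dice from integer confusion
counts. When ground truth and prediction are both empty the overlap
metrics are 1.0; when exactly one is empty they are 0.0. Dataset
aggregation reports both the mean of per-image metrics (primary, the
convention in this literature) and micro-pooled metrics from summed
counts, since reported results in this literature use either without
always saying which.

## Numerical core

No deep-learning framework is used: the network runs on a small
reverse-mode autodiff engine (`daunet.autodiff`) over numpy arrays, NHWC
layout, float32 parameters. Convolutions are im2col/GEMM with the patch
matrix rebuilt during backward; the 2 × 2 stride-2 transposed convolution
exploits its non-overlapping tiling. Adam (β = 0.9/0.999, ε = 1e-8) is the
default optimizer at learning rate 1e-4; weights are He-normal
(std = √(2/fan_in)) from a generator seeded by the model config, biases
zero, so builds and runs are bit-reproducible given a seed. Batch norm
uses batch statistics in training and running statistics (momentum 0.9)
at inference, making inference deterministic.

## Synthetic phantoms

The generator emulates the gross appearance of a breast B-scan:

* background: uniform noise smoothed with a Gaussian of σ = size/8,
  rescaled to [0.45, 0.8] — a smooth echogenicity field;
* lesion: one star-convex region, a rotated ellipse (aspect 0.7–1.4) whose
  polar radius is perturbed by harmonics 2–5 with amplitude
  `shape_irregularity` = 0.3; area fraction drawn from 0.02–0.25 of the
  image; interior intensity multiplied by 1 − `lesion_contrast`
  (default 0.35) — the hypoechoic appearance of tumors;
* speckle: unit-mean gamma multiplicative noise with variance
  `speckle_strength` = 0.15, the standard fully-developed-speckle model;
* point spread: Gaussian blur of σ = 1.5 px, then clipping to [0, 1] and
  quantization to the 8-bit grid so PNG round-trips are lossless.

The mask is the exact lesion indicator taken before the blur. Every
phantom is a pure function of (seed, index). What the phantoms do *not*
model: acoustic shadowing and enhancement, multiple or absent lesions,
heterogeneous internal echotexture, probe-dependent artifacts, and the
annotation noise of human raters. Tests passing on phantoms therefore
demonstrate that the architecture, losses, and training loop work as
specified — not that clinical-grade accuracy transfers to real BUSI/UDIAT
images, which require full-scale training on the real data.

## Data handling

Real data follows the BUSI directory dialect
(`<root>/<class>/<name>.png` + `<name>_mask*.png`); multiple mask files
are unioned, images are grayscale-converted, resized bilinearly to the
working resolution, rescaled to [0, 1]; masks are resized with
nearest-neighbor interpolation and re-binarized at 0.5. The tumor-free
"normal" class is excluded by default (the experiments used benign and
malignant cases), includable by flag. The train/val/test split is
70/10/20 ("70-10-20" admits two readings; 20 % test matches the larger
held-out evaluation and is the default, with the fractions fully
configurable), floor-rounded with the remainder to train; a k-fold
utility (default k = 5) partitions with test folds differing in size by
at most 1. All splits are seed-reproducible.

## Problem sizes in tests and the acceptance script

Chosen once as CPU-scale study conditions: oracle-equivalence checks run
100 trials on grids up to 4 × 4 × 4 against brute-force loop evaluations;
the ablation matrix builds all five variants at depth 3 / base 8 and runs
full 128 × 128 forward/backward passes; the overfit-capacity check trains
the depth-3/base-8 baseline on 8 phantoms (batch 8, Adam 1e-3) with early
stop at train Dice 0.92 within a 200-epoch cap; the acceptance script
additionally trains the full PCBAM + SWA variant on 24 phantoms at
64 × 64 — the resolution at which the N² position affinity is cheap —
and reports held-out metrics. The convergence checks use a learning rate
of 1e-3 rather than the 1e-4 production default because tiny-sample
memorization benefits from larger steps; full-scale training keeps 1e-4.

Because α = 0 makes the position-attention projections gradient-free at
the very first optimization step, the no-dead-branch test takes one Adam
step (α itself has nonzero gradient and moves off zero) and asserts every
parameter receives gradient at the second step.

## Known limitations

* Depth and width defaults are canonical U-Net proportions and parameter
  counts are regression-tested per variant, but they are this package's
  choice; comparable models in the literature rarely print theirs.
* Full-resolution position attention is O(N²) in time; at 128 × 128 skips
  it is streamed for memory but remains the computational bottleneck —
  expect ~10 s per training step per PAM-gated full-resolution skip on a
  single CPU.
* Headline clinical metrics (Dice ≈ 0.74 on BUSI-scale data) require the
  real datasets and GPU-scale training; nothing at phantom scale is
  claimed to reproduce them.
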