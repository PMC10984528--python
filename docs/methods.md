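# Methods

## Problem and model

PMFFNet segments ovarian tumors in B-mode ultrasound images: given an RGB
(or replicated-grayscale) frame, it produces a per-pixel lesion probability
and a binary mask. The architecture is an encoder–decoder:

* **Encoder (V2S).** A four-stage hybrid CNN–transformer pyramid. Each
  stage opens with a *reduction cell* (RC) — a strided convolutional stem
  plus a parallel dilated-convolution path that injects locality bias —
  followed by a stack of *normal cells* (NC): pre-norm windowed
  self-attention, a parallel 3×3 convolution, and a feed-forward block,
  all residually wired. Stage strides are 4/8/16/32, so a 384×384 input
  yields pyramid taps of spatial side 96/48/24/12; the tap is taken after
  the last NC of each stage (an empty NC stack taps the RC output).
* **Varied-Size Window Attention (VSA).** Queries attend within fixed
  W×W windows (W = 7 by default), but keys and values are re-sampled from
  per-head *varied* windows: a two-layer regression head pools each default
  window and predicts a log-scale and offset per head; key/value grids are
  sampled from the scaled/offset window by differentiable bilinear
  interpolation, with coordinates clamped to the feature extent. The
  regression output layer is zero-initialized, so an untrained VSA layer
  equals fixed-window attention *exactly* — a property the test suite
  asserts at 1e-5 relative tolerance.
* **MFB (multi-scale feature fusion).** At every pyramid scale, two
  parallel branches: the ERF branch (two dilated blocks, each three
  conv blocks at dilations 1, 2, 5 — a 33×33 effective footprint) and the
  LE branch (two residual blocks of plain 3×3 convs — a 9×9 footprint).
  Their 64-channel outputs are channel-concatenated (128) and fused by two
  residual blocks back to 64 channels.
* **Decoder.** Coarse-to-fine: upsample the deepest MFB map by exactly 2×
  (bilinear), concatenate with the next-shallower MFB output (64+64=128
  channels), apply two residual blocks (128→64, 64→64); repeat down to
  stride 4, then upsample to the input resolution. A prediction head (two
  residual blocks and a 1×1 convolution) emits one logit per pixel.

The block vocabulary: **CB** = 3×3 (possibly dilated) convolution → group
normalization (8 groups) → SiLU → residual addition, with a learned 1×1
projection when the channel count changes; **RB** = two CBs at dilation 1;
**DB** = three CBs at dilations 1, 2, 5.

## The HDC design calculus

Stacked dilated convolutions can leave input pixels entirely unused
("gridding"). The toolkit implements the standard hybrid-dilated-convolution
checks for a cascade of Z square stride-1 kernels of size K with dilations
d_1..d_Z (bottom first):

* the top-down recursion
  `M_i = max(M_{i+1} − 2 d_i, 2 d_i − M_{i+1}, d_i)`, seeded `M_Z = d_Z`;
  the design goals are `M_2 ≤ K` and `M_1 = 1` (adjacent coverage);
* hard rules: `M_2 ≤ K`, gcd of dilations = 1, no constant dilation > 1,
  `M_1 = 1`; a long strictly increasing cascade raises only a warning,
  since short increasing cascades such as (1, 2, 5) are legitimate;
* the closed-form receptive field `RF = 1 + Σ (K−1) d_i`;
* a brute-force oracle that back-propagates kernel-tap counts from one
  output pixel, yielding the exact per-input-pixel usage counts.

**Conservativeness.** Exhaustive enumeration (Z ≤ 3, K = 3, d ≤ 6) shows
the criterion is *sound but not complete*: every multi-layer cascade the
rules accept is gap-free, but some cascades the rules reject — e.g.
(2, 1) — still cover the input fully. The max-distance recursion is an
upper bound on the true gap, not an exact value. The property tests assert
the sound direction only. The usage-count oracle uses an infinite-canvas
convention (an interior output pixel); image boundaries are ignored.

## Default configuration and the parameter budget

The default configuration targets a 23 M-parameter budget — the scale at
which this architecture is competitive with far larger segmentation
backbones. Stage widths/depths are a design choice, fixed analytically so
the assembled default model lands at
23.3 M trainable parameters (rounding to 23 M): channels (64, 128, 256,
384), NC depths (2, 2, 7, 2), heads (2, 4, 8, 12) (head dimension 32
throughout), window 7, MLP ratio 2.75, MFB width 64. All of these are
config-exposed (`ModelConfig` / the YAML `model:` block). The VSA
regression heads add < 1 % of the total count.

Other genuinely open choices, resolved as follows:

* **MFB widths** are forced by the decoder's stated 128-channel fusion
  input: each branch projects backbone channels to 64 in its first CB, and
  fusion maps 128 → 64 → 64. Concatenation (not addition) merges ERF and
  LE, which makes the first fusion RB's 128-input match the decoder's RB
  pattern and loses neither branch.
* **Upsampling** is parameter-free bilinear (half-pixel-centre
  convention); fusion steps never upsample by more than 2×.
* **Relative position bias** is an index-based per-head table over
  query/key window positions, shared between fixed and varied windows
  (not geometrically re-interpolated for varied windows); this keeps the
  identity-initialization equivalence exact and is the simplest choice
  consistent with window attention practice.
* **Window padding.** Feature maps are zero-padded up to a multiple of the
  window side and cropped after attention; padded keys are not masked.
  The convention applies identically to fixed and varied windows. When a
  feature map is smaller than the window (the 12×12 stage with W = 7
  after further reduction), the window clamps to the map side.
* **Initialization**: truncated normal (std 0.02) for linear/table
  weights, fan-out-scaled normal for convolutions, normalization affine at
  identity, zero for the VSA regression output layer and for the final 1×1
  prediction convolution (so training starts from p = 0.5 everywhere).

## Loss and metrics

Training minimizes BCE + Dice. BCE is defined on probabilities with an
ε = 1e-7 clamp; the training path evaluates the algebraically identical
logits form (gradient σ(z) − A), because the clamped-probability form has
exactly zero gradient once a float32 sigmoid saturates — with it, a badly
scaled initialization freezes permanently. Dice uses the soft intersection
Σ A·B with smooth = 1 (so doubly-empty masks give loss 0), computed per
image and averaged over the batch; BCE averages over pixels then batch.

Evaluation thresholds probabilities at 0.5 and derives, per image, from the
confusion counts: Acc, IoU, Dice (smooth = 1 by default; `smooth=0` yields
the plain coefficient, which then satisfies Dice = 2·IoU/(1+IoU)),
precision and recall, and reports their arithmetic means (mAcc, mIoU,
mDice, mPr, mRe). Zero-denominator convention: both sides empty → 1;
one-sided → 0. Accuracy uses the full denominator TP+TN+FP+FN — correctly
classified pixels over all pixels.

## Optimization protocol

AdamW (β = 0.9/0.999, weight decay 0.01), initial lr 1e-4, batch 8,
100 epochs by default; augmentation is an independent 50 % horizontal and
50 % vertical flip. Validation mDice is computed every epoch; if it fails
to *strictly* exceed the best seen value for 10 consecutive epochs the lr
is halved (counter resets after a halving; no cooldown, no minimum delta).
The checkpoint with the best validation mDice is the final model. No
gradient clipping or warmup (both off, config-exposed). Training aborts
with a diagnostic on a non-finite loss. Everything is seeded: model
initialization, shuffling, augmentation draws.

## Numerical engine

No GPU framework is used: `pmffnet.nn` is a compact reverse-mode autograd
engine over float32 numpy arrays. Convolutions are evaluated as one GEMM
per kernel tap (9 for a 3×3 kernel), which keeps peak memory at one
feature map rather than a full im2col buffer; backward passes are
hand-derived and every fused kernel (convolution with stride/dilation,
group/layer norm, softmax, bilinear resize, bilinear grid sampling with
coordinate gradients, BCE-with-logits) is verified against central finite
differences in the test suite. Inference runs under a no-grad context that
skips graph construction.

## Synthetic phantoms: what they emulate, and what they do not

The phantom generator provides paired data with MMOTU-like directory
layout so the full pipeline runs without downloads. Each phantom is: a
smooth low-frequency echogenicity field (values 0.35–0.8) × unit-mean
gamma speckle (shape 4 — a standard multiplicative surrogate for fully
developed speckle); one hypoechoic lesion (intensity × 0.45) shaped as an
ellipse with a 3-harmonic sinusoidal boundary perturbation (relative
amplitude 0.12) and a Gaussian-blurred edge (σ = 2 px); image sides drawn
per phantom from a configurable range (default 192–320 px) to emulate
variable acquisition geometry. The mask is the exact perturbed-ellipse
interior — a single connected component, preserved by preprocessing. A
"shifted" corpus (contrast +0.25, speckle shape halved) emulates
evaluating on a different acquisition such as a CEUS-derived set.

Phantoms are deterministic in (config, seed) and lossless through the PNG
round-trip (bit-identical masks). They do **not** contain acoustic
shadowing, multiple or solid-papillary lesions, annotation noise, probe
artifacts, or inter-patient texture variability; passing the suite
demonstrates that the implementation is correct and trainable, not that
clinical-grade accuracy transfers to real ultrasound. Benchmark-level
metrics on real data require the MMOTU download and GPU-scale training,
which are out of scope here.

## Problem sizes used by the test suite

The unit and acceptance tests run the full default-width model only where
the property demands it (parameter budget; the 384×384 shape contract uses
default 64-channel MFB/decoder widths with a reduced-depth backbone, which
leaves every checked quantity — strides, tap sides, 128-channel fusion —
unchanged). Training-behaviour properties use a narrow variant (channels
8/16/32/64, depth 1 per stage, MFB width 16) on 96×96 phantoms: the
overfitting-capacity check trains it for 200 steps on 8 phantoms and
requires training mDice ≥ 0.95. These sizes are the package's chosen desk-
scale study conditions; the architecture is identical at every width.

## Known limitations

* CPU-only and single-threaded BLAS-bound; full-resolution default-width
  training is possible but slow — the engine is written for correctness,
  testability and desk-scale experiments, not throughput.
* Binary segmentation only (lesion vs background); the eight MMOTU tumor
  categories are not classified.
* Zero-padded (unmasked) attention windows at map edges; boundary windows
  therefore attend to a few zero keys.
* The plateau rule uses strict improvement with min-delta 0; extremely
  slow monotone improvement never halves the lr.
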