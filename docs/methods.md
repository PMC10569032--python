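# Methods

## Model

SW-UNet couples a convolutional encoder–decoder with a transformer
bottleneck. The convolutional path supplies the locality and weight-sharing
inductive bias that makes small medical datasets tractable; the transformer
bottleneck restores the long-range interactions that convolutions cannot
express within their receptive field.

**Encoder.** An initial pair of 3×3 convolutions (ReLU) at full resolution,
then `encoder_depth` stages of {stride-2 3×3 convolution doubling the width,
two 3×3 convolutions}. Widths start at `base_width = 16` and double per
stage. The downsampling operator is a strided convolution rather than
pooling so the reduction is learnable. With the default depth 2 a 1×128×128
input becomes a 64×32×32 map; skip features are kept at every level above
the bottom.

**Feature expansion / contraction.** One 3×3 convolution expands the bottom
map from 64 channels to the token dimension `d = 256`; rows and columns are
flattened row-major into a sequence z₀ of N = 32×32 = 1024 tokens. After the
transformer, the sequence is reshaped back to d×32×32 and two 3×3
convolutions (ReLU) contract it to the encoder's bottom shape so the decoder
and skip connections see exactly the shape the encoder produced.

**Sliding Window Transformer Block.** Four pre-norm residual sublayers —
windowed attention, feed-forward, shifted windowed attention, feed-forward —
followed by one global self-attention layer with residual that consolidates
information across all tokens. Windows are M×M = 4×4; the second attention
layer operates on the grid cyclically rolled up-left by s = 2 (half a
window), which is equivalent to moving the window lattice down-right. The
roll wraps opposite borders together, so the last row/column of windows mix
tokens that were never adjacent; additive masks (−10⁹ before softmax, which
is finite and therefore gradient-safe) zero those attention weights. On any
grid with both sides > M there are exactly three distinct non-trivial mask
patterns: bottom edge, right edge, corner.

Queries and keys are widened to `d_m = E·d` with E = 2 while values keep
dimension d ("width for depth": one wide block instead of a stack of
blocks). Attention uses 4 heads, scale 1/√(d_m/heads), and a free learnable
per-head bias B ∈ R^{M²×M²} added to the scores — the bias is stored as a
full matrix rather than a (2M−1)² relative-offset table, which is the
literal parameterization of the score equation and costs only 256 entries
per head at M = 4. The feed-forward sublayer is two affine maps with hidden
width 4d and exact (erf) GELU. The global layer is a standard multi-head
self-attention over all N = 1024 tokens with its own d×d projections and no
positional bias.

**Decoder.** Per level: a 3×3 stride-2 transposed convolution (implemented
as zero-insertion followed by a flipped-kernel convolution with asymmetric
padding, so the spatial side exactly doubles), concatenation with the skip
feature, then two 3×3 convolutions halving the width back. A final 1×1
convolution maps the 16-channel full-resolution map to `n_classes` logits.

**Ablation switches.** `use_sliding_window=False` replaces the shifted
masked attention with a second unshifted unmasked one; `encoder_depth`
ranges over 1–3 (the token grid is then 64², 32² or 16²). The depth default
is 2: that is the configuration whose token grid matches the 32×32 sequence
the complexity analysis assumes and the depth reported to score best.

## Numerical substrate

The network runs on a small reverse-mode automatic-differentiation engine
over float32 numpy arrays (`swunet.autodiff`): a `Tensor` with a backward
closure per operation and topological-order accumulation. Convolutions are
decomposed into one BLAS GEMM per kernel offset (nine for a 3×3 kernel),
which avoids materializing im2col buffers; transposed convolutions reuse the
same kernel via zero-stuffing. Softmax and layer normalization use the
standard max-shift / variance-epsilon (1e-5) stabilizations. Every
primitive's gradient is verified against central finite differences in the
test suite, and the assembled model is checked end-to-end the same way.

Weight initialization: truncated normal (std 0.02, clipped at 2σ) for
attention and affine weights, He fan-in scaling for convolutions, zeros for
all biases and for B. The optimizer is Adam (β₁ = 0.9, β₂ = 0.999,
eps = 1e-8) with bias correction.

## Loss

`L_Seg = α·L_Dice + β·L_Focal` with α = 0.8, β = 0.2. Probabilities come
from a channel softmax; each foreground class contributes a one-vs-rest soft
Dice term (smoothing ε = 1e-5, computed over the pooled batch) and a focal
term (γ = 2, probabilities clipped to [1e-7, 1−1e-7]); classes are averaged.
The focal equation is a **sum over pixels**, and the trainer uses that sum
form by default: the dense per-pixel cross-entropy-style gradient is what
keeps optimization away from the degenerate all-background solution when the
foreground occupies only ~1 % of the pixels, a regime in which the Dice term
alone saturates (softmax probabilities collapse to exact float32 zeros and
the gradient dies). A per-pixel mean reduction is available
(`LossConfig.reduction="mean"`) for reporting on a bounded scale. γ and the
clipping constant are not part of the reference protocol and are standard
choices.

Degenerate cases are fixed explicitly: empty-vs-empty masks have Dice 1 and
soft Dice loss exactly 0 (ε/ε); Hausdorff against an empty point set is an
explicit `UndefinedMetricError`, and per-case reports record undefined
entries and exclude them from aggregates rather than silently scoring 0.

## Metrics

Dice, accuracy, sensitivity and specificity come from one-vs-rest pixel
confusion counts. Hausdorff distances are computed between mask boundary
point sets (foreground pixels with a 4-neighbour outside), using KD-tree
nearest-neighbour queries; the directed distance aggregates per-point minima
at the 95th percentile for H95 (the maximum for the classical distance), and
the result is the max of the two directions. Distances are in pixel units.
Multi-class reporting is one-vs-rest per foreground class with unweighted
means, matching the five-column table layout (Accuracy, Dice, Sensitivity,
Specificity, H95).

## Preprocessing

Per-image min–max normalization into [0, 1]; a constant image maps to zeros
(the 0/0 case), preserving the range contract. No HU clipping is applied
before normalization. Sphere annotations (series id, world x/y/z mm,
diameter mm) are rasterized with `voxel = (world − origin)/spacing`,
0-based, no axis flips (the MetaImage convention); a sub-voxel diameter
still marks the centre voxel. Nodule-centred 128×128 crops clamp the window
at image borders instead of zero-padding, keeping real tissue context.
Resampling is bilinear for intensities and nearest-neighbour for label
masks. Splits are a seeded shuffle into 80/10/10 by floor, remainder to
train; partitions are checked disjoint on construction.

## Phantoms

The synthetic generator emulates the *structure* the pipeline assumes, not
CT physics. Nodule phantoms: a low-frequency smoothed-noise background in
[0.05, 0.35], `n_lesions` anisotropic Gaussian-profile ellipses (half-max
support defines the mask, so boundaries are curved and non-trivial for H95),
default peak contrast 0.45, additive Gaussian noise (σ = 0.08), clipped to
[0, 1]. Default lesion radii 4–12 px on a 128² patch, matching the scale of
nodules in cropped patches; one lesion per patch by default, as patches are
nodule-centred. Organ/tumor phantoms: one large bright ellipse (label 1,
radius ≈ 0.18–0.26 of the side) containing a small disk (label 2, radius
0.12–0.30 of the organ radius, offset bounded so containment holds by
construction), reproducing the tumor-much-smaller-than-organ imbalance; the
tumor/organ area ratio stays below 0.15.

What passing on phantoms shows: the architecture, gradients, losses,
metrics and orchestration are correct, and the model has the capacity to fit
small 2-D lesion structure. What it does not show: performance on real CT —
phantoms lack anatomy, acquisition noise structure, HU semantics and
inter-patient variability, so benchmark-level Dice/H95 claims are out of
scope here.

## Desk-scale protocol and problem sizes

The reference training protocol (Adam, lr 1e-5, batch 48, up to 100 epochs
with early stopping on validation loss, patience 15) is the estimator
default. That learning rate is appropriate for dataset-scale training; for
the desk-scale overfit sanity check (8 phantoms, single CPU) the package
uses Adam at 3e-3 with minibatch 4, the `"auto"` step schedule (rate ×0.3
once training Dice passes 0.8, ×0.1 past 0.92 — coarse localization first,
then fine boundary fitting), a global gradient-norm clip of 2e4 to absorb
the occasional order-of-magnitude spike of the sum-form focal gradient, up
to 160 epochs, and an optional `target_train_dice` stop once training Dice
crosses the requested level — a memorization check, not a performance
claim. Batch size auto-shrinks to
the dataset size with a logged notice when data are scarcer than the batch.
Ablation comparisons on phantoms run all arms from one shared seeded split
so the comparison is controlled; tests exercise them at reduced size
(32² inputs, token dimension 16) where the full shape chain still holds.

## Known limitations

Single 2-D slice processing only (no 3-D context); one SWTB rather than a
hierarchical multi-stage transformer; no pretrained weights; the analytic
FLOP report counts multiply–accumulates of convolutions, attention and
affine maps only (normalizations and elementwise ops excluded), so it is a
lower bound under one specific counting convention; CPU-only training makes
dataset-scale experiments slow, which is why phantom runs are deliberately
small.
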