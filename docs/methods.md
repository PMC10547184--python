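# Methods

This note documents what the package computes, the defaults it ships with,
and where genuinely open design choices were resolved.

## Problem setting

Cervical cytology screening images (Pap smear / liquid-based preparations)
contain many nuclei with overlapping, self-folded and blurred contours,
stain-color variation, and unlabeled impurities.  The task is binary nucleus
segmentation with instance recovery by connected components, evaluated both
per pixel and per object.

## Network

**Encoder.**  Seven resolution levels (six 2×2 max-poolings); each level is
two 3×3 conv + batch norm + ReLU blocks.  Channels double per level from
`base_channels` (64) up to a cap (512), i.e. 64,128,256,512,512,512,512 —
the uncapped doubling to level 7 would be 4096 channels, which no published
variant of this family uses; the cap follows standard feature-pyramid
practice.  Dropout (0.5) is applied at the deepest level only.  Inputs must
be divisible by 2⁶; the prediction path reflect-pads and records offsets
rather than cropping.

**Gating.**  Before fusion, each lateral feature is multiplied by
sigmoid(BN(1×1 conv)) with dropout inside the gate — a cheap spatial
attention that suppresses responses from irrelevant regions (impurities,
cytoplasm texture).

**CSFI.**  Levels 3–7 are projected to `fpn_channels` (64) by 1×1 convs,
gated, and passed through three stacked bidirectional pyramid layers.  Each
layer runs a top-down pass, `td_l = Conv(fuse(in_l, R_b(td_{l+1})))`, then a
bottom-up pass, `out_l = Conv(fuse(in_l, td_l, R_b(out_{l-1})))`, with
bilinear resizing `R_b` and fast normalized fusion
`Σ ReLU(vᵢ)xᵢ / (Σ ReLU(vⱼ) + e)`, `e = 1e-4`, one independent weight vector
per node, initialized to 1.  Fusion is scale-equivariant and its normalized
weights are non-negative with sum < 1 by construction.

**WCU.**  Two parallel compositions of orthogonal 1-D convolutions
(N×1∘1×N and 1×N∘N×1, N = 7 by default), summed.  Each branch has an N×N
effective receptive field at 2N/N² of the dense cost; the unit is applied to
the level-6 CSFI output and seeds both decoders at the deepest level.

**Dual decoder.**  Two coupled top-down chains over the used levels.
Segmentation: `S_l = Conv(fuse(csfi_l, R_b(S_{l+1}), R_b(csfi_{l+1})))`.
Boundary: `B_l = Conv(fuse(S_l, R_b(B_{l+1}), R_b(csfi_{l+1})))`.  The
coupling is strictly segmentation→boundary; zeroing every boundary
parameter leaves the segmentation output bit-identical (asserted in tests).
Each head ends with a refinement unit (3×3 conv, 1×1 conv), bilinear
upsampling to input resolution, a 1×1 projection and a sigmoid.  The final
nonlinearity is a sigmoid on a one-channel head (binary task); no softmax
head is provided.

## Losses

Per-image pixel sums, batch-averaged — this keeps the weights scale-free
across crop sizes.  Defaults: `w_seg = w_bou = 0.4`, smoothing `E = 1e-3`,
focal Tversky `α = 0.3, β = 0.7, γ = 4/3` (loss `(1−TI)^{1/γ}`), combo
`α = β = 0.5`, equal head balance.  Predictions are clipped to
`[1e-7, 1−1e-7]` inside cross-entropy terms, so all losses are finite at
probability extremes.  A bookkeeping subtlety: with `α = β = 0.5, γ = 1` the
Tversky denominator is half of (Σp + Σt), so Tversky at smoothing `E`
coincides *exactly* with the Dice score at smoothing `2E`; at equal `E` the
two agree only to the smoothing scale (~1e-4 on small maps).  The exact
identity is what the tests assert.

## Preprocessing

**Stain separation.**  Optical density `OD = −log((I + 1/255)/(1 + 1/255))`
on images in [0,1]; background pixels with ‖OD‖ < 0.15 are excluded; up to
5000 tissue pixels (fixed-stride subsample) enter a sparse non-negative
factorization `OD ≈ D·B` solved as dictionary learning with non-negative
unit-ball atoms and L1-penalized non-negative codes (sparsity weight 0.1).
Rows are unit-normalized and ordered hematoxylin-first by red-OD dominance
(hematoxylin transmits blue, hence absorbs red most strongly).  Robust
per-stain density maxima are the 99th percentile of the least-squares
densities.  Normalization rescales source densities by the ratio of target
to source maxima and recombines with the target basis — color changes,
structure does not (grayscale SSIM ≥ 0.8 on synthetic fixtures, asserted).
A plain NMF with an unnormalized L1 term was evaluated and rejected: it
does not recover the hematoxylin direction on ground-truthed synthetic
scenes; the unit-norm dictionary constraint is what makes the sparse
factorization identifiable here.

**Boundary enclosing.**  Ground-truth components truncated by the image
border are closed by tracing along the border between their border contacts
(through shared corners where a component touches two adjacent edges) and
filling the enclosed interior.  Interior components — including ones with
holes — pass through untouched, and the operation is idempotent.  Applied at
dataset-preparation time, before augmentation.  Limitation: if two distinct
components touch the same border edge with interleaved contact runs, the
min–max run fill could bridge them; this does not arise for convex nucleus
sections.

**Boundary targets.**  Union of per-instance morphological gradients
(dilation minus erosion, disk radius ⌈thickness/2⌉, default thickness 2 px).
Thinner targets destabilize the boundary loss on downsampled crops.  Pixels
between touching instances are always boundary.

**Augmentation.**  Geometric (h/v flips, resize-rescale, integer
translation, elastic deformation) applied identically to image and both
targets with nearest-neighbor mask interpolation; photometric (blur,
multiplicative and additive Gaussian noise, hue/saturation/contrast) applied
to the image only.  Elastic displacement fields whose Jacobian would fold
the grid are rescaled with a logged warning.  Flips and integer translations
preserve mask cardinality exactly; rescaling preserves it to analytic area
scaling up to nearest-neighbor rim rounding (~a few percent).

## Synthetic data

The generator emulates the statistical structure of liquid-based cytology
fields: 5–60 rotated elliptical nuclei (semi-axes 8–28 px, eccentricity up
to 0.85) with eosin-tinted cytoplasm halos (2.2× the nucleus ellipse),
partial overlap (a new nucleus may intersect existing ones with probability
0.25, with a minimum center distance so no instance is fully occluded),
border truncation (p = 0.15), unlabeled impurity blobs, Gaussian blur
(σ ≤ 1.2) and additive noise (σ ≤ 0.03).  Stain densities are near-pure per
compartment (nucleus: hematoxylin ≈ 1.0, eosin 0.05; cytoplasm: eosin 0.35,
hematoxylin 0.03) and rendered to RGB by Beer–Lambert with unit-norm H&E
optical-density vectors, which makes the scenes an exact fixture for the
stain-separation round trip.  Scenes are pure functions of their parameters
(per-scene seeds derived arithmetically from a base seed).

What the generator does **not** model: chromatin texture, out-of-focus
planes, mucus/inflammation, real stain batch effects, or the 0.32 μm pixel
scale as a physical unit.  Green tests on synthetic scenes therefore
demonstrate correctness of the algorithms and trainability of the network,
not clinical performance.

## Training and evaluation

SGD with learning rate 1e-3, momentum 0.9, weight decay 5e-4, batch size 10,
BN running-statistics decay 0.99 (single-device; multi-device synchrony is
out of scope), random 256² training crops, 512² evaluation, constant
learning rate, early stopping on validation Dice (patience 15) with the
best-validation checkpoint retained.  Checkpoints are self-describing
(weights + full config + seed).  Splits are a seeded shuffled 80/10/10.

After very short training runs the slow BN decay leaves running statistics
behind the weights; `runtime.refresh_batchnorm_stats` re-estimates them with
a single momentum-0 calibration pass (weights untouched) before inference.

Object-level evaluation: predicted instances are 8-connected components;
matching is greedy one-to-one by descending pairwise DSC among pairs with
DSC > 0.7, ties broken by ascending (gt, pred) id for determinism.
`recall_o = matched/n_gt`, `FNRo = 1 − recall_o`, and object accuracy
defaults to union normalization `matched/(n_gt + n_pred − matched)`
(`union_normalized=False` switches to matched/n_pred).  Both empty masks
count as Dice 1; undefined ratios are reported as NaN, never as silent 0.

## Problem sizes used in the shipped checks

The test-suite and the reproduction script run the network at reduced width
(base 8 channels, 16 pyramid channels, 64² inputs) — the smallest
configuration that exercises all seven levels — and overfit four synthetic
scenes with the composite loss; full-width 512² inference is checked
shape-only.  The smoke run reaches training Dice ≥ 0.95 within 300 SGD steps
at learning rate 0.05 (the reference rate 1e-3 is tuned for long schedules
on real data, not for a 300-step overfit).

## Known limitations

- The engine is CPU-only and single-device; no mixed precision, no GPU.
- `fit_stain_model` determinism is exact up to floating-point reduction
  order under threaded BLAS (tested with tolerance 1e-8).
- Greedy DSC matching is not guaranteed maximum-cardinality in adversarial
  overlap configurations (tests compare it against exhaustive assignment on
  small instances, where they agree).
- Multi-class (cytoplasm) heads and boundary-distance metrics are out of
  scope.
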