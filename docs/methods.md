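# Methods

`earcount` implements density-map-augmented instance segmentation for
counting wheat ears in field imagery: a YOLACT-style one-stage
prototype/coefficient segmentation network whose backbone carries
GeM-pooled CBAM attention blocks and whose feature pyramid feeds an
auxiliary Gaussian density-map branch. This note records the model, its
assumptions, the parameters that matter, the numerical choices, and what
the synthetic benchmark does and does not show.

## Density-map targets

Each annotated ear contributes one isotropic 2-D Gaussian bump centered
at its polygon centroid:

    D(a, b) = Σ_i  1/(2πσ²) · exp(−((a − a_i)² + (b − b_i)²) / (2σ²))

Each kernel integrates to ≈ 1, so the map's total mass estimates the
instance count. Choices:

- **Center definition.** The area-weighted polygon centroid, not the
  bbox center: it is invariant to vertex density and to the starting
  vertex of the outline.
- **σ (kernel width).** Not derivable from the annotation format; the
  default is 8 px at 1024² resolution — roughly half an ear's minor axis
  at that imaging scale — and scales proportionally at other input sizes
  (2 px at the 128² test scale). A fixed σ is used for all instances;
  per-instance geometry-adaptive σ is available as an option but off by
  default, since the target definition uses a single σ.
- **Truncation.** Kernels are evaluated within `4σ` of the center
  (square window) and are zero beyond; the omitted tail mass is < 4e−4
  per target. Truncation is purely an efficiency device.
- **Border handling.** Truncated border Gaussians are *not*
  renormalized: the superposition formula as defined has no
  renormalization, so targets closer than ~4σ to an image border
  contribute less than unit mass and the map undercounts them. This
  bias is documented rather than corrected; the mass-conservation
  guarantee (|mass − N|/N ≤ 1e−3) holds for centers ≥ 4σ from every
  border.
- **Sampling.** D is evaluated at integer pixel coordinates
  (a = column, b = row), matching the discrete formula.
- **Rescaling across FPN levels.** The full-resolution map is generated
  once and rescaled to each pyramid level by block-sum pooling (exactly
  mass-conserving for integer factors) or bilinear resampling followed
  by global mass renormalization otherwise. Generating per-level maps
  by rescaling — rather than re-evaluating the kernel per level — keeps
  the mass identical across levels by construction.

## GeM pooling and the attention block

Generalized-mean (GeM) pooling aggregates activations by the power mean
`GeM_p(x) = ((1/n) Σ x_i^p)^(1/p)`; p = 1 is average pooling and
p → ∞ approaches max pooling. The CBAM attention block gates a feature
map sequentially — channel gate, then spatial gate — and in the variant
here **every pooling operator inside CBAM is a GeM pool**:

- One GeM descriptor per branch (not the avg+max concatenation of
  classic CBAM): the channel MLP input is C, the spatial convolution
  input is 1 channel. This follows from replacing *all* pooling layers
  with GeM and having exactly one exponent per branch.
- Exponents initialize at p = 11 (channel branch) and p = 19 (spatial
  branch) and are learnable per-branch scalars, floored at p ≥ 1 by
  projection after every optimizer step (the power mean is monotone and
  well-behaved only for p ≥ 1).
- Spatial gate convolution is 7×7 with same-padding; channel MLP
  bottleneck is C/r with r = 8 (tiny) or 16 (full), clamped to ≥ 1.
- Numerics: inputs are clamped to ≥ 1e−6 before exponentiation so real
  p-th powers and their gradients are defined, and the power mean is
  computed as `m · ((1/n) Σ (x/m)^p)^(1/p)` with m = max(x) held
  constant — an exact identity for any fixed m > 0 that prevents
  overflow at large p (the naive form overflows in float64 near
  p ≈ 500 for activations of a few units).

A bound worth knowing when testing: `GeM_p ≥ max · n^(−1/p)`, so "p = 64
is within 5% of the max" is guaranteed only for n ≤ 26 pooled values;
the checks use 5×5 maps.

## Network

- **Backbones.** `resnet101` (bottleneck residual stages of depths
  3/4/23/3) is the full-scale fidelity preset; `tiny` is a few-stage
  reduced-width plain-conv variant for CPU-scale training and tests.
  Normalization layers are omitted throughout (convolutions carry
  biases); at the scale of the tiny runs this trains stably and keeps
  the numerics simple.
- **Attention placement.** One GeM-CBAM block after each backbone stage
  that feeds the FPN (3 taps for both presets).
- **FPN.** Strides (4, 8, 16) for `tiny` at 128² input, (8, 16, 32) for
  the full preset; 1×1 laterals, nearest 2× top-down, 3×3 smoothing.
- **Heads.** A shared prediction tower per level emits per-prior
  objectness, class scores (background + ear), SSD-encoded box offsets
  (variances 0.1/0.2) and k mask coefficients. Prototypes come from a
  Protonet on the finest level (k = 8 tiny / 32 full) at stride 4.
  Objectness biases initialize at −2 so early training is not flooded
  with false positives.
- **Priors.** One prior per aspect ratio {1, 1/2, 2} per position.
  Per-level aspect-1 side lengths for the tiny preset are (10, 14, 20)
  px, chosen from the bbox statistics of the synthetic ears (mean side
  ≈ 10–11 px at 128²); the full preset uses 3× the stride. Priors are
  laid out position-major then aspect, matching the head's output
  layout — an invariant worth testing, since a mismatched layout trains
  to garbage while some losses still decrease.
- **Density branch.** Per FPN level, two 3×3 convolutions
  (width 16 tiny) with a softplus output; the bias of the last
  convolution initializes at −3 (softplus ≈ 0.05) so predicted density
  starts near zero.

## Losses

    L_total = 1.0·L_cla + 1.5·(L_obj + L_box) + 6.125·L_seg + w_d·L_density

- **Matching.** Priors with IoU ≥ 0.5 to a ground-truth box are
  positive, < 0.4 negative, in between ignored; every gt is guaranteed
  its best-IoU prior as a positive even below threshold.
- **L_obj.** Binary cross-entropy on objectness over positives plus the
  hardest negatives at 3:1 (hard-negative mining — the plain sum over
  all priors is dominated by thousands of easy negatives and stalls
  learning), averaged over the counted priors.
- **L_box.** Smooth-L1 on encoded offsets over positives, averaged by
  positive count; zero when there are no positives.
- **L_cla.** Cross-entropy over counted priors, background label for
  negatives, mean-reduced.
- **L_seg.** Per-pixel BCE between the assembled mask
  `sigmoid(Σ_j coeff_j · prototype_j)` and the rasterized gt polygon
  mask at prototype resolution, cropped to the gt bbox and averaged
  over bbox pixels, then over positives (at most 32 positives scored
  per image, sampled beyond that, to bound cost). A separate semantic
  head is not added; the per-pixel segmentation term is realized as
  this assembled-mask loss.
- **L_density.** Mean over FPN levels of the density-map MSE
  `(1/N_pix) Σ (d_i − gt_i)²`. The weight w_d defaults to 1.0, which
  keeps L_density within an order of magnitude of the other terms.

The logged total is recomposed from the component floats by exactly the
weighted sum above, so the decomposition identity holds to better than
1e−10 on every step.

## Inference and density fusion

Boxes are decoded from priors, scored by `sigmoid(objectness) ×
softmax-foreground`, and the predicted density modulates the score:

    s' = s · (1 + α·d_local) / (1 + α·d_max)

with d_local the finest-level density sampled at the box center, d_max
the map maximum, α = 1 by default; α = 0 recovers the plain detection
score. This is one concrete, ablatable realization of "linearly
combining" the density map with the detection branch; fusion into the
prototype branch was the alternative reading and is not implemented.
Greedy NMS at IoU 0.5 (deterministic, not the approximate fast variant),
masks assembled for survivors, thresholded at 0.5. The count readout is
the number of detections at or above the score threshold; the density
integral is reported alongside as a diagnostic.

## Training

SGD with momentum 0.9 from a base learning rate of 0.001 at full scale;
the CPU-scale smoke runs use 0.02 (a few hundred iterations at batch 8
cannot move a freshly initialized network at the full-scale rate), with
global gradient-norm clipping at 50. Batch size 8. All randomness —
initialization, batch sampling, mask subsampling — derives from explicit
seeds; training histories are bitwise reproducible on CPU. A non-finite
loss aborts immediately, naming the first offending component.

## Synthetic scenes

The generator renders golden-hued, spikelet-textured, rotated-ellipse
"ears" with an awn fringe over a green vegetation background, at four
density levels with count ranges 5–15 / 15–40 / 40–80 / 80–150 per
scene. Ear size scales with resolution (major axis 96–150 px at 1024²,
hence 12–19 px at the 128² test scale), so the same counts apply at any
size. The cluttered background adds elongated leaf-like strokes drawn
from an ear-similar hue range, emulating the field situation where
leaves are mistaken for ears. Ground truth is exact: 16-vertex polygon
approximations of each ellipse, centers ≥ minor-axis from the borders,
placement by rejection sampling with a level-dependent minimum
separation (denser levels tolerate more overlap). Everything derives
from one seed.

What the scenes do *not* model: photometric variation (illumination,
soil, camera), perspective, true occlusion by leaves (clutter never
occludes ears), ear-shape diversity across cultivars, and annotation
noise. Passing the end-to-end benchmark therefore shows that the
training loop, the density branch, and the counting readout work as a
system — not that the model generalizes to real field imagery, which
requires full-scale training on real datasets.

## The smoke benchmark and problem sizes

The end-to-end check trains the tiny model on 32 scenes at 128²
(levels 1–2) for 200 SGD iterations, then counts on 16 held-out level-1
scenes. The detection-score threshold for counting is calibrated on the
*training* scenes (grid search minimizing count RMSE there) and applied
unchanged to the held-out scenes. The ablation comparison (full model
vs. no-density variant) runs 10 seeded repeats at 64²/60 iterations.
These sizes exercise every branch of the model at desk scale; they are
the package's own benchmark configuration, not a claim about full-scale
behavior.

## Known limitations

- Counting metrics treat the density integral as secondary; at the
  smoke scale the detection count is the better-calibrated readout.
- Bias is defined as mean(y − ŷ) — with this sign a *positive* Bias
  means under-counting. The convention is stated literally in the
  formula and kept, although prose elsewhere sometimes implies the
  opposite sign.
- mAP here is mask-AP (IoU on instance masks); box-AP is not reported.
- The COCO reader supports polygon segmentations only; RLE raises.
- No pretrained weights: at full scale the architecture supports the
  ResNet-101 preset, but this package never loads external weights.
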