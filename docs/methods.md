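# Methods

## Problem and model

The task is three-class per-pixel segmentation of top-down field imagery:
class 0 background (soil), class 1 corn, class 2 weed. The network is an
encoder–decoder ("RDS" = ResNeXt + Deformable + scSE):

**Encoder — ResNeXt-50 (32×4d).** A 7×7/stride-2 stem (64 channels) followed
by four stages of bottleneck blocks with repeats 3/4/6/3. Each bottleneck is
1×1 reduce → grouped 3×3 (cardinality 32) → 1×1 expand, with a projection
shortcut where shape changes. Bottleneck widths are 128/256/512/1024
(group width 4, doubling per stage) and stage outputs are
256/512/1024/2048 channels. On a 224×224 input the stem + stages emit the
feature pyramid 112/56/28/14/7 used by the skip connections. Grouped
convolution gives the accuracy of a wide bottleneck at 1/32 of its 3×3
weight count; the equivalence of the grouped kernel to 32 independent paths
is tested explicitly.

**Decoder.** Four up-blocks, each: bilinear ×2 upsample → concatenate the
skip → two 3×3 conv+BN+ReLU. Counting from the bottleneck, layer 1 (the
deepest, smallest-resolution layer) replaces its first 3×3 convolution with a
deformable convolution; layers 2–4 end with an scSE block. A 1×1 head emits
3 logits per pixel.

**Deformable convolution.** A standard 3×3 convolution computes
`y(p) = Σ_k w_k · x(p + p_k)` over the fixed grid offsets `p_k`. The
deformable version adds a learned per-position, per-tap offset
`y(p) = Σ_k w_k · x(p + p_k + Δp_k(p))`, with `x` evaluated by bilinear
interpolation since offsets are fractional. The offset field has 2 channels
(Δrow, Δcol) per tap — 18 channels for a 3×3 kernel — produced by a
zero-initialized companion convolution, so at initialization the layer is
exactly a standard convolution and deformation is learned from there.
Sampling outside the padded support reads zeros.

**scSE.** Two gates applied to the same feature map and summed:
cSE squeezes spatially (global average pool → bottleneck MLP, reduction 2 →
sigmoid) and re-weights channels; sSE squeezes channel-wise (1×1 conv →
sigmoid) and re-weights pixels. With all parameters zero, each gate is
exactly ½, so `scse(x) = x`: a useful identity oracle, but also a gradient
dead point, so trainable layers initialize with small He-scaled weights
(a `zero_init` flag exists for testing).

**Presets.** `unet` (plain U-net baseline: VGG-ish encoder, no deformable, no
scSE), `unet_1` (+ResNeXt encoder), `unet_12` (+deformable layer 1),
`unet_123` = `rds_unet` (+scSE layers 2–4). The ladder isolates each
component's contribution; toggling a component never perturbs the
initialization of shared components (tested by weight equality).

## Synthetic scenes

Labeled field imagery is expensive, so the package generates its own. Each
scene is: value-noise soil texture (brown tones, mild vignetting), 1–3 corn
plants as dark-green lobed rosettes (4–7 elongated leaves around a center,
radius drawn from `corn_scale`), and several weeds as small, lighter-green
irregular blobs (`weed_scale`). Masks are rendered from the same geometry,
so ground truth is exact. Per-scene seeds derive from a `SeedSequence`, so
datasets are bit-reproducible and individual scenes are regenerable.

What it emulates: the visual statistics that make the task non-trivial —
small objects, irregular outlines, color overlap between classes, occlusion
of weeds by corn leaves, textured background. What it does not: real optics
(no perspective, no specular highlights, no motion blur), real plant
morphology, growth stages, or lighting/weather variation. Scores on
synthetic scenes therefore validate the learning machinery, not field
performance.

## Data pipeline

Datasets are stored in Pascal-VOC layout (`JPEGImages/`,
`SegmentationClass/` with palette PNGs, `ImageSets/Segmentation/*.txt`).
`labelme_to_voc` converts labelme polygon JSON (labels corn/weed/grass;
pixel-center even-odd rasterization). `prepare` expands a dataset to a
target count by round-robin re-augmenting source images — default 500 → 4000
— with four strategies each applied independently with probability 0.5:
horizontal mirror, rotation (90/180/270, inverse mapping about the pixel
center, nearest-neighbor for masks), brightness scaling, and Gaussian
blur/noise (photometric ops never touch masks). Splits are 8:2 train+val :
test, then 8:2 train : val (2560/640/800 at 4000); all replicates of a
source image stay in the source's split, so augmentation cannot leak across
the evaluation boundary.

## Training protocol

Dice loss over one-hot truth vs softmax probabilities, averaged over
classes, with ε = 1e-5 in numerator and denominator; optimizer Adam with
learning rate 0.001, β₁ = 0.9, β₂ = 0.999, decoupled-style L2 weight decay
1e-4 added to the gradient; batch size 4; 100 epochs by default. Images are
channel-standardized with statistics fitted on the training split only.
`fit_arrays` supports `max_steps` and `stop_at_train_miou` for bounded
smoke runs. Checkpoints are `.npz` files holding every parameter plus
normalizer, config and variant metadata; reloading reproduces forward
outputs bit-exactly.

## Evaluation

MIoU, macro precision and macro recall from a 3×3 confusion matrix; classes
absent from both prediction and truth are excluded from the macro average
(an all-empty matrix raises rather than fabricating a score). The metric
implementation is pinned against an exact-rational (`fractions.Fraction`)
per-pixel oracle in the tests. `measure_fps` times warm forward passes;
`render_overlay` blends corn green / weed red onto the image for visual
inspection.

## Numerical choices

- The network stack is a reverse-mode autograd over NumPy: conv2d via
  im2col + BLAS matmul (grouped variant per group), bilinear upsampling as
  two interpolation-matrix contractions, float32 parameters.
- The Adam update for the full model (~74 M parameters) is memory-bound;
  it is fused into a single-pass Numba kernel (`fastmath=False` so results
  match the pure-NumPy fallback path, which is kept for environments
  without Numba).
- "Zero offsets = standard convolution" is bit-exact per sampling tap;
  summing 9 taps in a different association order than a reference
  implementation leaves ~1e-15 discrepancies, which tests acknowledge with
  rtol = 1e-12 rather than asserting bitwise equality of full kernels.
- Gradients of every custom op (conv, pooling, upsample, batchnorm,
  deformable conv including its offset field, scSE) are verified against
  central finite differences.

## Limitations

- CPU-only NumPy training is slow: the full `rds_unet` at 224×224 and the
  default 100-epoch protocol is an hours-scale run. The test suite and
  acceptance script therefore exercise the identical code paths at reduced
  image size, scene count and epoch count; the full-scale run is available
  through the CLI but is not part of the automated checks.
- Synthetic scenes validate mechanism, not agronomy (see above); all
  reported scores are on generated data.
- The ablation trend (each added component improving MIoU) is a
  statistical statement that needs multi-seed full-scale runs to settle;
  `scripts/acceptance.py` reports a reduced-scale two-endpoint comparison
  as information, and `rdsunet ablate` runs the full four-row protocol.
- Deformable offsets are unconstrained; very large learned offsets sample
  mostly zero padding. In practice offsets stay small because the layer
  starts at the standard-convolution identity.
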