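# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the bundled
experiments do and do not demonstrate.

## Detector model

The detector treats detection as one regression pass over a spatial
grid. A square RGB input is mapped by a convolutional stack to an
`S × S × (C + B·5)` tensor: per grid cell, `B = 5` anchor slots of five
numbers each (center offsets `t_x, t_y`, log-size offsets `t_w, t_h`,
objectness `t_o`) plus `C` shared class scores (`C = 1` for the fruit
models, one species per trained model). Decoding puts the center at
`σ(t_x) + c_x` cell units — inside the emitting cell by construction —
and the size at `prior · e^{t_w}`. Model capacity assumptions: fruits
are near-circular, near-uniform in size, and at most one object of the
class per grid cell; two fruits whose centers fall in the same cell with
the same best-matching prior cannot both be predicted. The fine grid
(26 × 26 rather than the customary 13 × 13) exists precisely to make
cells fruit-sized and this collision rare.

**Decode convention.** The size equations are implemented as anchor
prior × exponential offset. Writing them in terms of the ground-truth
size would make inference impossible (the ground truth is unknown at
prediction time), so the standard anchor-prior convention of the base
single-shot family is used.

**Grid arithmetic.** Layer sizes follow `n' = (n + 2·pad − F)/S + 1`,
and the builder rejects any chain producing a non-integer size. 26 does
not divide 608, so no all-stride-2 chain reaches a 26-grid from a
608-input; the shipped specs use three stride-2 stages
(608 → 304 → 152 → 76) and one stride-3, kernel-3, pad-1 stage
(76 → 26). Consequently the pixel size of a cell, 608/26 ≈ 23.4 px, is
not an integer; decoding uses the real value throughout. Stride-2
stages use 4 × 4 kernels: with an even input size, a stride-2 window
must have even extent for the reduction to stay integral (a 3 × 3 or
5 × 5 kernel with symmetric padding does not).

**Variants.** `fine_grid_spec` (M1) is the 23-layer deep model with max
pooling; `shallow_spec` (M2) keeps the 26-grid but has 11 layers and no
pooling, downsampling purely by strided convolutions — roughly half the
depth, for embedded-speed use. `tiny_spec` (208-input, 13-grid, 6
layers) is the same design scaled to CPU-minute training runs; channel
widths double per stage and cap at 512 (128 for tiny), the only free
choice in the layer tables. Layer counts include conv, pool and the
1 × 1 detect head.

**Activation.** PReLU `max(αx, x)` with α = 0.1, fixed (not trained) by
default. α must lie in (0, 1).

## Loss and training

No canonical objective exists for this family beyond "squared-error
multi-part", so the loss is the standard one: for each ground truth, the
responsible slot is its center cell plus the prior of highest IoU
against the truth's size (both centered at the origin); squared errors
on `σ(t_x), σ(t_y)` against the in-cell offset and on `t_w, t_h` against
log size ratios (weight 5), objectness `σ(t_o)` pulled to 1 on
responsible slots (weight 1) and to 0 elsewhere (weight 0.5, so empty
sky does not drown the signal), class score pulled to 1 on object cells
(weight 1). All weights are configurable. If two truths claim the same
slot, the later one wins (rare by design of the fine grid). Gradients
are computed analytically through the sigmoid and verified against
numerical differentiation in the test suite.

Training uses Adam at learning rate 0.002 with 60 optimizer steps per
epoch (the named optimizer is taken at face value; a generic
gradient-descent reading of the same configuration would contradict
it), batch size 8, sampling the dataset with replacement; 35 epochs is
the full-scale default, 5 for fine-tuning from a checkpoint. Transfer
modes: `freeze_backbone=True` trains only the detect head (fixed
feature extractor — frozen weights are bit-identical afterwards, and the
test suite checks this); initializing from a checkpoint without freezing
is fine-tuning. Weight init is He-normal, seeded; training is exactly
reproducible on CPU for a fixed seed.

The network engine (im2col convolution, pooling, PReLU, Adam, manual
backprop) is implemented in NumPy inside the package, in float32. It is
deliberately minimal — no autodiff, no GPU — sized to the problem: the
CPU-scale experiment trains in about a minute on one core.

## Anchors

Priors are not derivable from first principles; the defaults are five
square priors spanning 0.5–8 cell units, wide enough that near-uniform
fruit sizes always have a close prior. `fit_anchors` offers k-means in
(w, h) space under the 1 − IoU metric for fitting priors to labeled
data when rigor matters.

## Synthetic scenes

The generator emulates a stylized orchard view: a bluish sky band over
brown soil (horizon at half height), 150–400 dark-green ellipses as
foliage, and 30–70 light-green or light-red circles (radius 14–28 px on
a 608 canvas) as fruits, drawn last. Every fruit contributes its
circle's tight bounding square as a ground-truth box, so labels are
exact. Only color names are inherent to the scene description; the
concrete RGB ranges (e.g. sky R 100–160, G 150–200, B 220–255) are this
package's defaults and are fully overridable. A fruit overdrawn by
later fruits keeps its label only while ≥ 20% of its disc remains
visible, mirroring the field practice of labeling only visible fruit;
fruit-over-fruit occlusion can be disabled entirely.

What the scenes do **not** emulate: lighting variation and shadows,
leaf occlusion *in front of* fruits, perspective and depth, texture,
camera noise, fruit color gradation. Passing the bundled experiments
therefore shows the pipeline learns and localizes correctly — it says
nothing about accuracy on real orchard photographs, which depends on
real training data.

**CPU-scale conditions.** The scaled experiment uses a 208-px canvas
with the 13-grid tiny detector. Geometry scales linearly (fruit radius
5–10 px); the fruit count scales with grid-cell count (13²/26² = 1/4 of
30–70 → 8–16 per scene) so the fraction of occupied cells — what the
detector actually resolves — matches the full-scale setting; leaf count
scales with area. The recovery experiment trains on 200 scenes and
evaluates on 50 held-out scenes, 10 epochs of 25 steps (≈ one pass over
the data per epoch), and requires held-out F1 ≥ 0.5 at IoU 0.5 with an
upward early-epoch trend. These sizes make the experiment a
minutes-scale, single-core computation.

## Augmentation

Seven op kinds: horizontal flip, scale (0.7–1.3 about the center),
rotation (±15°), perspective (corner jitter ±5% of the frame), color
jitter (±30 per channel), contrast (0.7–1.3 about the mean), Gaussian
noise (σ 2–12). Ranges are this package's defaults — mild,
label-preserving perturbations — and are configurable per call.
Geometric ops move boxes through the same 3 × 3 homography and replace
rotated boxes by their axis-aligned hull (both label dialects are
axis-aligned); boxes are then clipped, and a box keeping under 20% of
its area is dropped. Photometric ops never touch boxes. `augment_dataset`
draws op kinds uniformly per variant from a seeded generator; the
number of variants per image `k` is a plain parameter (default 3) —
nothing in the package hard-codes a total.

## Tiling (splitter/joiner)

`split` partitions a frame into row-major square tiles (1216 → exactly
four 608 tiles), zero-padding right/bottom edges to a multiple when
needed and recording the padding. `join` translates per-tile boxes by
their tile origin. A fruit cut by a seam is detected once per adjacent
tile as two abutting half-boxes whose mutual IoU is small, so plain NMS
cannot merge them; instead, every box within 4 px of an interior border
is mirror-extended across that border by its own extent, and pairs of
extensions with IoU > 0.3 are replaced by the union of the original
boxes (higher confidence kept). Setting the seam margin to 0 disables
merging — without it every seam-straddling fruit double-counts, which
would bias cropload upward. Tiling generalizes to R × C grids; the
defaults reproduce the 2 × 2 case.

## Evaluation

Greedy confidence-ordered one-to-one matching (the VOC protocol) at
IoU ≥ 0.5; pooled counts over the dataset (micro-average — one
confusion matrix for the whole set) before computing precision, recall
and F1. Mean IoU averages over matched pairs by default; `strict_iou`
also counts a zero for every unmatched detection and truth, for the
reading in which misses penalize the overlap score too. Greedy matching
can in principle fall short of the optimal assignment on adversarial
overlap patterns; the test suite compares it with brute-force optimal
assignment on a constructed ambiguous instance.

## Cropload

`cropload = d·(2 − F1)·(1 + t)` with `d` the detection count, `F1` the
model's evaluation F1 (supplied by the evaluation module or by hand) and
`t` the hidden-fruit fraction of the training system; the calibrated
values are 0.05 and 0.1. The reported visibility range of 85–95%
would suggest `t` up to 0.15; the calibrated pair is used as given.
The result is left unrounded; a `--round` flag applies round-half-up.
`F1 = 0` is rejected (the correction is undefined there), and the
estimate is monotone: increasing in `d` and `t`, decreasing in `F1`.

## Numerical choices

Float32 weights and activations; sigmoid logits clipped to ±60 before
exponentiation (σ saturates exactly at float32 precision well inside
that range); He-normal init; NMS ties broken by input order; boxes are
0-based half-open pixel intervals internally, with VOC's 1-based
inclusive corners and DARKNET's 6-decimal normalized text handled at
the I/O boundary (re-reading a DARKNET file clamps sub-pixel rounding
spill at the frame edge). Per-scene dataset seeds are spawned from the
master seed via a seed sequence, so datasets are reproducible
file-hash-for-file-hash.

## Known limitations

One class per trained model; at most one detection per (cell, prior)
pair; no rotated boxes or masks; the NumPy engine is single-core and
unsuitable for training the full 608-px variants at realistic dataset
sizes; synthetic-scene realism as discussed above; greedy matching is
protocol-faithful but not assignment-optimal.
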