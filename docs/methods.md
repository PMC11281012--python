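# Methods

## Problem setting

A dual-stream detector consumes pixel-aligned RGB and depth images of
orchard scenes and predicts class-labelled boxes for fruit under four
occlusion conditions (unshaded, leaf-, branch- and fruit-shaded). The
package's core is the pair of fusion blocks that combine the two modality
streams at every backbone stage; everything else (backbone stages, neck,
head, training loop) is deliberately simple scaffolding that makes the
blocks executable, trainable and measurable on one CPU.

## LGEM — local–global enhancement

Inputs are two aligned grids `RGB, Depth ∈ R^{b×c×h×w}` (three for the
tri-modal variant). The block:

1. concatenates the streams on channels (`2c`, or `3c` tri-modally);
2. compresses them to a one-channel local weight map with a convolutional
   bottleneck MLP — main branch `Conv(2c→c/2) → Conv(c/2→c/2) → ReLU →
   Conv(c/2→1) → LayerNorm`, plus a residual `Conv(2c→1)`; all
   convolutions are 3×3, stride 1, padding 1, with bias. The layer norm is
   applied to the main branch only, before the residual addition, exactly
   as the block is defined. `c` must be even so the `c/2` bottleneck is an
   integer;
3. flattens the map to a token sequence — spatial positions are tokens,
   the (single) channel is the feature axis — and applies single-head
   scaled dot-product self-attention, `softmax(q·kᵀ/√d_k)·v` with `d_k`
   the token feature dimension (1 here). This gives every pixel of the
   weight map a global receptive field;
4. reshapes back (the exact inverse of the flatten) and refines with a
   miniature 1×1 convolution, yielding `E_global`;
5. multiplies both (all) streams elementwise by `E_global`, the single
   weight channel broadcast over feature channels.

Invariants asserted in the test suite: spatial shape is preserved
end-to-end, both weight maps are exactly one channel, flatten/reshape is a
bit-exact round trip, attention rows sum to 1, multiplying `E_global` by a
scalar scales both outputs by exactly that scalar, and the composed
forward equals an independent chaining of the five primitives to 1e-6.

## RFAM — rough–fine fusion

*Rough stage.* Both grids are flattened to `(b, h·w, c)` token sequences
and cross-attention is computed in both directions — RGB queries attend
depth keys/values and vice versa, with temperature `√c`. Two bottleneck
MLPs with independent parameters (same shape as the LGEM MLP but mapping
`c → c/2 → c/2 → c`) transform the attended sequences; the sequences are
treated as `(b, c, h·w, 1)` column images for the 3×3 convolutions, then
reshaped back to grids `RGB_R`, `Depth_R`. Cross-attention semantically
fills each modality's gaps (depth silhouette voids, light-polluted RGB
regions) from the other modality.

*Fine stage (coordinate attention).* Each coarse grid is max-pooled over
height into a width profile `(b,c,w,1)` and over width into a height
profile `(b,c,1,h)` — the pooling subscript names the *retained* axis, as
the printed output shapes force. The four profiles are spliced (height
profiles transposed first) into one `(b,c,2w+2h,1)` vector in the fixed
order `[RGB_w | Depth_w | T(RGB_h) | T(Depth_h)]`, transformed by a single
shared bottleneck MLP, and split back; splice/split are exact mutual
inverses when the MLP is the identity. Finally

    Fused = RGB_R ⊛ RGB_w ⊛ RGB_h + Depth_R ⊛ Depth_w ⊛ Depth_h.

`⊛` is realised as broadcast multiplication of each directional profile
across its collapsed axis — the standard coordinate-attention semantics.
A literal chain of matrix products would change the spatial shape (and is
only summable for square grids), which would make the per-stage fusion
output unusable by the neck; the literal variant is nevertheless exposed
behind `fine_fuse(..., literal_matmul=True)` for experimentation. The
printed fine-fusion equations carry no sigmoid, so none is applied by
default; `RFAM(..., bounded=True)` squashes the profiles through a sigmoid
for users wanting classic bounded coordinate attention.

The tri-modal extension is `f = RFAM(RFAM(x, y), RFAM(x, z))` with three
independently parameterised instances, anchored on the first modality.

## Detection scaffold

Each modality has its own weight-independent extractor: a stride-4 stem
and three stages (strides 8/16/32) of strided conv + residual blocks. The
stages are plain residual stacks — the scaffold's contract is topological
(three stages, per-stage enhancement and fusion, auxiliary flow), not a
replica of any published backbone, so parameter totals are not comparable
with full-scale detectors. LGEM is embedded at each stage; RFAM fuses each
stage pair into one pyramid level. With both blocks disabled the fusion
degenerates to channel concatenation plus a 1×1 projection (the natural
"plain dual-stream" baseline). The neck max-pool-merges the deepest level
(3×3 and 5×5 same-size pools, concatenated, 1×1-projected) and runs a
top-down pathway with nearest-neighbour upsampling; per-scale anchor-free
heads output 4 box offsets, 1 objectness logit and one logit per class.

The optional auxiliary branch takes the raw RGB through a pass-through
placeholder into a half-width stream; the deepest fused level is linearly
split into per-stage channel groups (1×1 convolution), each group is
nearest-upsampled to its stage's resolution and spliced onto the auxiliary
features, and light heads produce predictions that enter the loss with
weight 0.25. The branch is skipped at inference.

**Stability choices.** Activations in the scaffold are SiLU (the smooth
`x·σ(x)` used throughout modern conv-detector blocks); with ReLU, the
multiplicative fusion weights drove entire neck channels into the dead
regime early in training. Each stage and each fused pyramid level ends in
a LayerNorm (statistics per sample over channel×space, affine per
channel): the unbounded multiplicative weights of both blocks otherwise
give the three pyramid levels dynamic ranges differing by two orders of
magnitude. LGEM's refine convolution starts near identity (weight 0.1,
bias 1) so `E_global ≈ 1` initially — a zero-mean initial gate would
randomly sign-flip features and stall optimisation. Gradients are clipped
to global norm 10.

**Parameter counting.** `count_params` evaluates the closed form
`Σ_conv (K·in + 1)·out + Σ_fc (in + 1)·out` (K = kernel area; every
convolution carries a bias) and is tested for exact integer equality
against enumeration of the conv/FC weight and bias elements. LayerNorm
affine parameters (a few dozen scalars) are outside the conv/FC formula by
construction; `Module.num_params()` enumerates everything.
`measure_speed` reports wall-clock milliseconds per sample (`T/N`) and is
a report-only utility — timing is hardware-bound and never asserted.

## Training procedure

Anchor-free assignment: each ground-truth box goes to the pyramid scale
matching its size (`√(wh)` < 24 px → stride 8, < 56 px → stride 16, else
stride 32) and to the cell containing its centre; a cell keeps only its
first object. The loss is binary cross-entropy on objectness over all
cells with positive weight 24 (positives are 1–3 cells in hundreds),
binary cross-entropy on class logits at positive cells, and an IoU term
`1 − IoU(decoded box, target)` at positive cells with weight 2. Boxes
decode as sigmoid-bounded centre offsets within the cell and
`exp`-scaled sizes (clamped to `e^±3`) against a 2-stride prior.

The optimiser is Adam with the recipe defaults: base learning rate 0.01,
first-moment coefficient (momentum) 0.975, decoupled weight decay 5e-4,
3 warm-up epochs rising linearly from 0.1× the base rate, then linear
decay back to 0.1× by the final epoch; 200 epochs, batch 32, 640×640
input in the full-scale configuration. Mosaic augmentation — four pairs
resized into the quadrants around a centre sampled uniformly from the
central half of the canvas, with the identical geometric transform
applied to RGB (bilinear), depth/IR (nearest-neighbour, so no depth
values are invented across object boundaries) and labels — is active
until the final `close_mosaic` = 30 epochs. Training is fully seeded:
same seed, same data, same machine gives bit-identical logs; a NaN loss
aborts with a diagnostic. Inference applies a confidence threshold
(default 0.25) and per-class greedy NMS at IoU 0.5 — both conventions,
configurable.

## Synthetic data

The generator emulates the statistical structure of a young-fruit orchard
dataset: per scene, 2–5 elliptical fruits with centre-biased Gaussian
placement and small boxes; a Leaf-heavy default class mix
(0.25/0.45/0.15/0.15 over False/Leaf/Branch/Fruit) reflecting canopy
imbalance; class-dependent occluders (leaf blobs, branch strokes, an
overlapping unlabelled fruit); a depth raster with per-object distance
(nearer = smaller value), additive noise, and 0 as the invalid-depth
sentinel; optional dark (gain 0.35 + noise) or glare (saturated elliptical
patch + halo) corruption of the RGB channel only, since depth is robust to
lighting; annular depth voids carved with probability `depth_void_rate` on
the 0.8–1.1 relative-radius band of each fruit; and an optional
near-constant IR raster mimicking the negligible thermal emission of
fruit. Datasets are written in YOLO layout with an 8:1:1 split and a
manifest of per-scene seeds from which regeneration is bit-exact.

What the generator does *not* emulate: photorealistic texture, real sensor
noise statistics, perspective and scale variation, motion blur, or
correlated backgrounds. Passing the end-to-end test therefore shows the
machinery trains and localises on clean geometry; it says nothing about
accuracy on real orchard imagery.

## Evaluation

Greedy confidence-ordered matching assigns each prediction to the
highest-IoU unmatched same-class ground truth with IoU strictly above the
threshold. AP is the area under the all-point-interpolated PR curve
(interpolation variant chosen and fixed here; a 101-point variant would
differ in the third decimal at these sample sizes); mAP averages AP over
classes present in the ground truth; mAP50:95 averages mAP over exactly
the ten thresholds 0.50–0.95. A literal accuracy-style ratio
`(TP+TN)/(TP+TN+FP+FN)` with TN = 0 (true negatives are undefined in
detection) is kept as `average_precision(..., method="accuracy")` for
completeness; it is not used by any aggregate. The confidence sweep
recomputes micro-averaged P/R/F1 over a threshold grid and reports the
best-F1 operating point.

## Desk-scale benchmark and problem sizes

`run_toy_benchmark` fixes the end-to-end study conditions: 64 easy
128×128 scenes (1–3 unshaded fruits of 14–20 px radius, normal light, no
depth voids), 16 held-out validation scenes, the default model
(stage channels 16/24/32, depth 1, ~69k conv/FC parameters), 20 epochs.
The desk-scale recipe is batch 2 and learning rate 5e-3 — small batches
buy optimisation steps, which matter more than gradient quality at this
scale. Epoch losses are summarised by a trailing 5-epoch moving average
(full windows only) because batch-2 epoch losses are noisy. With seeds
0/1/2 the benchmark reaches validation mAP50 0.73/0.88/0.79 in about one
minute per run. Unit and oracle tests use grids with `h·w ≤ 256` and
`c ≤ 16`; attention memory grows as `(h·w)²`, so full-scale 640×640
stride-8 grids are outside the intended desk-scale envelope.

## Numerical choices and limitations

- All computation is float64; oracle equivalences are asserted at 1e-6,
  reversibility and identity limits bit-exactly.
- `softmax` subtracts the row maximum; sigmoids clamp logits at ±60.
- Ties in max-pooling split the gradient equally among the tied entries.
- Precision and recall are defined as 0 when their denominators are 0.
- The matching protocol is greedy, not optimal assignment; on crowded
  scenes with overlapping ground truths it can undercount TP relative to
  a maximum bipartite matching.
- The autograd engine is eager and unoptimised; it exists for
  transparency, not speed. Conv backward materialises full im2col
  buffers, so memory grows linearly with batch × spatial size.
- Checkpoints are NumPy `.npz` archives of named parameters plus the
  model configuration; they are runtime artefacts, not exchange formats.
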