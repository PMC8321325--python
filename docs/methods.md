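# Methods

## Problem and model

Dermoscopic lesion segmentation assigns each pixel of a skin image to
pigmented-lesion foreground or healthy-skin background.  The difficulty is
concentrated at the boundary: pigment borders are often fuzzy and
low-contrast, and the images carry distractors (hairs, glue halos, ruler
marks) that correlate with neither class.  The network implemented here
attacks the boundary directly by learning **edge prediction as an auxiliary
task** next to mask prediction, with three components:

1. **Encoder.**  A truncated bottleneck residual network (stages Conv1–Conv4).
   Three 2× reductions (stride-2 stem conv, stem max-pool, stride-2 entry of
   Conv3) bring an S-pixel input to S/8.  Conv4 uses stride 1 with dilation 2
   in its 3×3 convolutions, so the deepest features keep the S/8 resolution.
   A pyramid pooling module (bins 1, 2, 3, 6; per-bin 1×1 reduction to a
   quarter of the output width, bilinear upsampling, concatenation with the
   Conv4 map, 3×3 fusion) produces the shared feature map F.  At default
   configuration (448-px input, width 1) the stages measure
   (64,224,224), (256,112,112), (512,56,56), (1024,56,56) and F = (128,56,56).

2. **Cross-connected dual decoder.**  Two parallel branches — mask (Seg) and
   edge — each a chain of three channel-preserving residual up-blocks
   (1×1 → full width, 3×3 → 32-channel bottleneck, 1×1 → full width, skip
   add, then 2× bilinear upsampling).  After every stage each branch's input
   to the next stage is the element-wise **sum** of both branches' outputs.
   Summation is forced by the printed channel widths: every block declares
   the same input width as output width, which concatenation would double.
   Because the fusion is symmetric, both stage-k+1 blocks receive the same
   fused input; the branches still differ through their weights.  The edge
   ground truth is derived from the mask (morphological gradient band), so
   the auxiliary task costs no extra labels.

3. **Shared multi-scale aggregation head (MSFA).**  Each pyramid scale gets a
   prediction head (3×3 conv at full width + BN + ReLU, 3×3 conv to one
   channel); a fourth map is a direct 1×1 convolution of the finest level.
   The four logit maps are bilinearly upsampled to the input size, stacked
   (4,S,S) and combined by a learned 1×1 convolution; one sigmoid is applied
   at the very end.  Logits — not probabilities — are aggregated: the 1×1
   combination is then a learned affine weighting of per-scale predictions
   and the final output stays in (0,1).  The same head object serves both
   branches (shared parameters), which pushes mask and edge predictions
   toward similar quality.

## Loss

Per image with N pixels (Npos foreground, Nneg background) and prediction h:

    l = -(1/N) Σ [ w1·y·log h + w0·(1-y)·log(1-h) ],   w1 = Nneg/N, w0 = Npos/N

The rarer class carries the larger weight and w0 + w1 = 1.  Weights are
recomputed per image (the definition refers to *a* ground-truth mask); a
batch loss is the mean of per-image losses.  Degenerate masks are well
defined — the vanished class has weight 0 and no pixels; predictions are
clamped to [1e-7, 1-1e-7] only to protect the logarithm.  The joint
objective is

    L = α·L_seg + L_edge,  α = 0.05 by default,

with α multiplying the segmentation term, kept exactly as the reference
design specifies; the edge target is far sparser, so its class-balanced loss
runs larger and α keeps the two terms in a similar range.  An α sweep
(0.005, 0.05, 0.25, 0.5) is exposed through the `loss.alpha` config key.

## Training protocol

Adam, batch 8, initial learning rate 1e-4 decaying per epoch by γ = 0.9,
30 epochs at full scale.  Online augmentation per sample: horizontal and
vertical flips (p = 0.5), centred crop at a scale drawn from [0.75, 1.25],
rotation in [-20°, 20°], crop to the ground-truth bounding box expanded by
50 px with zero padding, and a rigid moving-least-squares warp, followed by
a resize to the input size.  Images are interpolated bilinearly, masks with
nearest neighbour (so they remain binary), and the edge target is re-derived
after the geometry.  Checkpoint selection is by validation Jaccard index.
At test time only the mask output is used; test-time augmentation averages
the inverse-mapped predictions over the six axis-aligned dihedral transforms
(identity, three rotations, two flips), whose inverses are bit-exact.

## Numerical and design choices

* **NN substrate.**  The network runs on a compact numpy reverse-mode
  autodiff engine written for this package (`lesionseg.nn`): dense conv2d as
  shift-and-matmul with arbitrary stride/dilation, batch norm with running
  statistics, max pooling, separable bilinear/adaptive-average resampling as
  exact linear operators, and Adam.  Every primitive is validated against
  central finite differences in the test suite; the dense convolution is
  additionally cross-checked against `scipy.ndimage.correlate`.
* **Rigid MLS warp.**  Similarity-constrained moving least squares with
  inverse-square-distance weights, applied as a backward mapping (handles
  p+d → p define the sampling field).  The smooth coordinate field is
  evaluated on a stride-2 lattice and expanded by bilinear interpolation,
  which is exact for affine fields — global rigid motions (identity,
  translation, rotation) are reproduced to ~1e-14.  Handles sit on a 4×4
  grid with displacements up to 5% of the image side by default.
* **Edge thickness.**  2 px by default (at 448-px resolution): thin enough to
  be an edge, thick enough to survive downscaling and give the balanced loss
  a non-empty positive class.  `derive_edge` uses dilation XOR erosion with a
  3×3 cross; thickness 1 reduces to the inner one-pixel boundary.
* **Upsampling** everywhere is parameter-free bilinear interpolation with
  half-pixel centres; decoder fusion happens on the already-upsampled
  previous-stage outputs so spatial sizes match.
* **Degenerate metric denominators** score 1 when the condition is vacuously
  met (e.g. sensitivity on an image with no foreground and no false alarms)
  and 0 otherwise; such rows are flagged in the CSV report.  Dataset scores
  are means of per-image metrics; the binarization threshold is 0.5.
* **Initialisation** is He-normal (no pretrained weights are downloaded;
  `Module.load_state_dict` is the hook for externally supplied encoder
  weights).
* **Batch averaging order**: the per-image class weights make the loss
  non-separable across a batch; the batch loss is defined as the mean of
  per-image losses.

## Synthetic data and the desk-scale study

The generator (`lesionseg.synth`) emulates the traits that make real
dermoscopy hard: a connected star-shaped lesion (ellipse with low-frequency
radial perturbation, area fraction kept in [0.05, 0.6]), darker pigment over
a skin-toned background with smooth illumination, boundary fuzziness as a
Gaussian-blurred compositing matte, contrast as the pigment/skin separation,
and optional hair / glue / ruler artifacts composited **after** the mask is
fixed, so distractors never change the ground truth.  Difficulty presets
span easy (sharp, high-contrast — a plain Otsu threshold reaches JA ≥ 0.9)
to hard (fuzzy, low-contrast, artifact-laden); Otsu performance degrades
monotonically across the presets, which is the generator's calibration
check.  What the generator does **not** emulate: real pigment texture
(networks, globules), multi-lesion scenes, vignetting, colour charts, or
annotation noise — so passing the synthetic study demonstrates that the
architecture, losses and pipeline work end to end, not clinical-grade
accuracy on real dermoscopy.

The desk-scale study (`lesionseg.study`) scales the architecture, not the
design: 64-px input, all widths at 1/8, two Conv4 blocks — the same /8
feature ratio and module structure as the full model.  It trains on 200 easy
96-px synthetic lesions for 15 epochs (batch 8) with the full augmentation
suite, selects by validation JA (24 images) and evaluates 30 held-out
images with TTA.  Two protocol constants are re-expressed for this regime:
the ground-truth crop margin scales with image size (50 px at 448 ≈ 11 px at
96), and the learning rate is 1e-3 — the conventional Adam rate for a small
network trained from scratch; the published 1e-4 is a fine-tuning rate for a
pretrained encoder and underfits a randomly initialised model in 15 epochs.
Both choices are fixed once in `lesionseg/study.py`.

Ablation variants are constructible exactly as in the source design:
`seg_only` (backbone + Seg subnet + direct 1×1 head), `seg_edge` (both
cross-connected subnets, direct head) and `full` (adds the shared MSFA
head).

## Known limitations

* CPU-only; a full-width 448-px forward pass takes tens of seconds, so the
  default configuration is audited for shape correctness rather than
  trained here.
* No pretrained encoder: results at full scale would require externally
  supplied weights and GPU-scale training.
* The probability resize in `predict` is bilinear on probabilities (then
  thresholded), which can smooth very thin structures at extreme upscaling
  factors.
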