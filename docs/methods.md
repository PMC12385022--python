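# Methods

## Problem and pipeline

Lumbar spondylolisthesis (LS) is the anterior displacement of a vertebra
relative to the vertebra (or sacrum) below it. On a lateral radiograph it is
quantified by the Meyerding scheme: the slip distance of the upper vertebra,
expressed as a fraction of the sagittal diameter of the lower vertebra's
superior endplate, is binned into quartiles (grade I up to 1/4, II up to
2/4, III up to 3/4, IV beyond). A study is positive when any level reaches
grade I or higher.

`spondylograde` automates this reading in four stages:

1. **Segmentation** — an edge-attention PointRend U-Net labels each pixel as
   background, L1–L5 or sacrum.
2. **Landmarks** — per structure: largest 8-connected component → convex
   hull of pixel centres → minimum-area rotated bounding rectangle → each
   rectangle corner snapped to its nearest hull vertex. The rectangle's long
   axis is the endplate axis; the long side with smaller image *y* is the
   superior endplate. The sacrum contributes only its two superior corners.
3. **Grading** — at each interface (L1/L2 … L5/S1) the upper vertebra's
   lower-posterior corner is projected onto the line through the lower
   structure's superior endplate; the anterior-positive offset from the
   posterior corner, divided by the endplate length, is the slip ratio,
   which is then binned.
4. **Reporting** — per-level measurements, the maximum grade and its level,
   and the binary diagnosis.

Because the ratio is a quotient of lengths measured in the same image, the
grading is invariant to translation, rotation and uniform scaling, and
independent of pixel spacing — which is why no physical calibration is
needed anywhere in the pipeline.

## Segmentation model

The network is a 4-stage U-Net. Each encoder block applies two 3×3
convolutions, each followed by batch normalisation and ReLU, then a 2×2
max-pool that quarters the feature-map area; over four blocks the bottleneck
is 1/16 of the input on each side (inputs are reflect-padded to a multiple
of 16 and cropped back). Decoder blocks mirror this with 2×2/stride-2
transpose convolutions.

**Edge attention.** At every skip connection a Canny edge map is computed
from the channel-mean of the encoder features (min-max rescaled to 0–255),
concatenated to them as an extra channel, projected back to the decoder
width by a learnable 1×1 convolution, and added element-wise to the decoder
features. The edge channel is a non-differentiable input; gradients flow
through the feature channels of the concatenation. Canny thresholds
(default 50/150 on the 0–255 scale, Gaussian σ = 1) are configuration.

**PointRend.** A 3-layer point-wise MLP re-predicts the pixels whose top-two
logit margin is smallest, from the full-resolution stage-1 encoder features
concatenated with the coarse logits at those pixels. At inference the
refinement runs for a configurable number of rounds; only the selected
pixels change, all others are bit-identical. Ties in the margin are broken
by a stable sort on the flat pixel index. The head is trained with an
auxiliary focal loss on the selected points (switchable); an untrained head
would corrupt rather than refine, so the switch defaults to on.

**Loss and optimisation.** Training minimises the focal loss
−α_c (1−p_c)^γ log p_c averaged over pixels, with γ = 2 and α defaulting to
inverse class-frequency weights computed from the training masks — the
background dominates a radiograph, and the focal/weighted combination keeps
the six bone classes from being drowned out. The optimiser is Adam
(default learning rate 1e-4, batch 16, 500 iterations, decoupled L2
penalty 1e-5); an optional cosine schedule decays the rate to zero over the
run. Early stopping halts training when the loss changes by less than 10%
(relative) across the trailing 50 iterations; both numbers are
configuration, and a window of 0 disables the rule. A single configuration
seed drives parameter initialisation and batch shuffling; inference is
deterministic.

**Prediction post-processing.** The argmax mask receives a one-iteration
per-label binary opening. Convex-hull vertices are extremely sensitive to
single-pixel boundary protrusions, and this light opening removes them
while moving true corners by at most the structuring element's radius. It
can be disabled (`predict(..., clean=False)`); exact rasterised masks do
not need it and the ground-truth grading path does not use it.

## Synthetic phantoms

No public clinical data exist for this task, so the package ships a phantom
generator that every downstream stage is tested against. A phantom is five
stacked rectangular vertebral bodies above a trapezoidal sacrum. Slip at an
interface is injected as a pure in-plane translation of the upper body along
the direction of the lower body's superior endplate, so the requested ratio
is realised *exactly* in the continuous corner coordinates stored as ground
truth; a global tilt is applied as a rotation of the whole column, which
provably leaves every ratio unchanged. The rendered image is a per-class
base intensity (background 40; L1–L5 190→130 in steps; sacrum 110 on the
8-bit scale, vertebrae differing slightly as their projected density does),
modulated by a low-frequency multiplicative Gaussian texture field (relative
amplitude 0.15) and additive Gaussian noise (SD 6 grey levels). Default
geometry: 256×192 px frame, 72×28 px bodies, 8 px disc gaps; a `scaled`
constructor shrinks the geometry proportionally for smaller frames.

The dataset sampler draws a study grade from a configurable mix, picks the
slipped interface uniformly among the five, and samples the ratio uniformly
inside the Meyerding band at least 0.02 from each band edge; all other
levels carry exactly zero slip — the generator's idealisation of a healthy
level. Tilt is uniform in ±5°. Fixed seeds give byte-identical images,
masks and manifests.

What the phantoms deliberately do **not** emulate: projective (DRR)
rendering, soft-tissue and bowel-gas texture, endplate curvature and
osteophytes, vertebral wedging, scoliosis, implants, and exposure
variation. Passing the phantom studies therefore demonstrates that the
architecture, geometry and grading logic are correct and learnable — not
that the shipped defaults would reach clinical performance on real
radiographs, which would require training on real annotated data at full
resolution.

## Small-scale studies

Two studies, runnable from `spondylograde.experiments` and recomputed by
`scripts/acceptance.py`, size the problem for a single CPU:

- **Grade recovery** (`grade_recovery_study`): 300 phantoms at the default
  256×192 resolution, graded from their ground-truth masks (segmentation
  bypassed). With ratios clear of every boundary by 0.02, corner
  rasterisation error (≲1 px on a 72 px endplate) cannot flip a bin, and
  agreement with truth is exact.
- **Learnability** (`tiny_learnability_study`): 100 training phantoms at
  96×96, 200 iterations. At this scale the study uses encoder channels
  (12, 24, 48, 96), batch 8, learning rate 3e-3 with cosine decay, the
  point-head loss on 128 points, and a PointRend inference budget of 2048
  points (scaled by image area) over 3 rounds — all chosen for single-CPU
  turnaround; the full iteration budget is run (early stopping off).
  Training grade mix mirrors the clinical imbalance (~90% normal, slipped
  studies dominated by grades I–II); the 50 held-out phantoms are uniform
  over the five classes so every grade is probed. Reported: mean foreground
  Dice over the six structures, and end-to-end study-grade accuracy
  (predicted mask → landmarks → Meyerding).

## Numerical and design choices

- **Coordinates**: 0-based (x, y) pixel centres, x rightward, y downward,
  everywhere. Anterior defaults to decreasing x (patient facing image-left)
  and is configurable, since radiograph laterality varies.
- **Bounding rectangle**: minimum-area rotated rectangle by default —
  axis-aligned corners are anatomically wrong on a tilted spine — with an
  axis-aligned mode available (`rect_mode="axis"`).
- **Corner snapping ties**: nearest hull vertex by Euclidean distance, ties
  broken by smaller y then smaller x.
- **Components**: 8-connectivity; components under 20 px are rejected as
  debris. Structures missing from a mask are flagged, not fatal; a study is
  an error only when *no* adjacent pair is measurable.
- **Normal threshold**: Meyerding defines no grade 0, so a slip ratio at or
  below `normal_epsilon` (default 0.05, configurable) is reported Normal;
  boundaries are inclusive on the lower grade (a ratio of exactly 1/4 is
  grade I). Negative (retro-) displacement is clamped to 0 and flagged.
- **McNemar variant**: continuity-corrected χ² with 1 df when the discordant
  total is ≥ 25, exact two-sided binomial below; the threshold is an
  argument.
- **F1 aggregation**: macro-average over grade classes by default,
  micro-average available; zero-denominator precision/recall/F1 are 0 with
  an explicit degeneracy flag.
- **Focal-loss numerics**: probabilities are clamped at 1e-12 before the
  log (clamps are logged); the training path computes the loss from logits
  via log-softmax for stability.
- **Training batches**: seeded shuffled epochs; a trailing partial batch is
  reshuffled into the next epoch rather than run short.

## Known limitations

- The autodiff engine implements exactly the operations this network needs;
  it is single-threaded NumPy and not a general deep-learning framework.
- The learnability study's accuracy ceiling is set by corner noise: a 1–2 px
  corner error on a 36 px endplate is a ratio error of up to ~0.05, which is
  the entire Normal band. Higher-resolution phantoms (as in the grade-
  recovery study) remove this ceiling. For the same reason the study's
  grading accuracy varies by several points between seeds — the quality of
  a 200-iteration training run on 100 images is itself a random variable,
  and small Dice differences translate directly into boundary-corner noise.
- Only translational anterior slip is modelled and graded; slip angle,
  pelvic parameters and dynamic studies are out of scope, as is
  retrolisthesis (flagged, not graded).
- When several levels slip simultaneously, the report lists all levels and
  the maximum; which single level a clinician would headline is a
  convention the package does not impose.
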