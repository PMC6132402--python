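# Methods

## Problem and pipeline

Inserting a needle under 3D ultrasound guidance is hard because the needle is
a thin, sometimes partially invisible structure occupying roughly one voxel
in every few thousand, surrounded by speckle and by bright anatomical
structures (bone, fascia) that mimic its appearance. `usneedle` implements a
three-stage localization pipeline:

1. **Voxel detection** by one of two interchangeable learned detectors:
   a triplanar-patch CNN classifier or a 2.5D thick-slice fully
   convolutional segmenter with multi-view fusion.
2. **Axis estimation**: RANSAC fitting of a fixed-diameter cylinder to the
   detected voxel centres, with principal-axis refinement and tip
   designation.
3. **Visualization**: extraction of the plane that contains the whole needle
   and is perpendicular to the coronal (lateral–elevational) planes — the
   in-plane view a clinician steers by.

Volumes are stored in `(lateral, axial, elevational)` order with isotropic
voxel size (0.20–0.36 mm/voxel is the intended regime). Voxel centres sit at
`origin + (index + 0.5) · voxel_size`; all geometric metrics are computed in
millimetres in this frame.

## Detectors

### Triplanar patch CNN

Each voxel is described by three orthogonal 21×21 cross-sections centred on
it (≈ 4.2×4.2 mm at 0.2 mm/voxel, sized to contain a clinical needle of
0.72–1.47 mm diameter plus context). Two variants exist: **ShareCNN**
convolves all three planes with a single shared filter bank; **IndepCNN**
uses one bank per plane. Both use four unpadded 3×3 convolutions of 32, 48,
64 and 96 filters (spatial size 21→19→17→15→13, no pooling — pooling costs
localization accuracy at voxel scale), concatenate the three 13×13×96 maps,
and classify through fully connected stages of 128, 64 and 2 units with
softmax. Dropout 0.5 regularizes the first two fully connected stages.
`count_conv_parameters` reports the filters × kernel-area convention
(2160 shared / 6480 independent); the conventional input-depth-weighted
count is exposed separately as `count_conv_weights`.

Training is RMSProp on categorical cross-entropy, learning rate 1e-4 for the
initial phase and 1e-5 for update phases, batch 128, early stopping on a
held-out patch split (patience 5, at most 100 epochs by default). Because of
the ~1:3000 class imbalance, negatives are first downsampled to match the
positives; patches are augmented by random 90° rotations about the axial
axis (implemented by extracting from the rotated volume, which is exact).
Then `bootstrap_rounds` of hard-negative resampling run: the trained model
re-classifies its own training volumes, false positives are harvested ranked
by predicted needle probability ("most-aggressive" background voxels, ties
kept in scan order), and the same weights continue training at the lower
update rate on all positives plus the harvested negatives (topped up with
fresh random negatives when too few are harvested). Patch intensities are
standardized by their source volume's mean and standard deviation.

Patch centres near the volume border are zero-padded by default; a `strict`
extraction mode exists for callers that prefer to skip the border band
(voxels within half a patch of the border are then undetectable).

### 2.5D thick-slice FCN

The volume is decomposed into cross-sections perpendicular to the lateral
and to the elevational axis, stepping one voxel at a time. Each section is
presented as a 3-channel **thick slice**: the processing section plus the
parallel sections at ±`d` mm (default `d` = 2.0 mm; neighbours are clamped
at the volume border so channel count is always 3). `d = 0` degenerates to a
single-slice input and serves as the baseline condition of the gap sweep.
The per-pixel label of a slice is the truth mask restricted to the
processing plane; neighbour channels supply context only.

One network with shared weights (**ShareFCN**) serves both directions. The
encoder is a VGG-19-style convolutional stack (blocks of 2, 2, 4, 4, 4
same-padded 3×3 convolutions of 64, 128, 256, 512, 512 channels, each block
followed by 2× max pooling with recorded argmax indices; total downsampling
×32). The decoder upsamples by factors 2, 2 and 8 with convolution stages of
512, 256 and 2 filters. The first two upsamplings are index unpoolings
through the pool-5 and pool-4 masks. The final ×8 stage uses the pool-3
indices for its first ×2 (the only remaining pooling mask whose channel
count matches the decoder at that depth) and nearest-neighbour upsampling
for the residual ×4; a fully nearest-neighbour decoder is available as
`upsample_mode="nearest"`. Skip connections tap the encoder before the 4th
and 5th pools and are fused by addition after a channel-matching 1×1
convolution. Dropout (0.85) regularizes the two deepest encoder convolution
stages of the full-width network.

Training follows Adam at 1e-4 with batch size one slice and softmax
cross-entropy. Volumes are augmented by `n_rotations` arbitrary-angle
rotations about the axial axis *before* slice extraction (default 10), and
needle-free sections are downsampled to match needle-containing ones. At
small widths, individual training trajectories occasionally collapse into
an under-confident local optimum; `restarts` (default 1) trains several
independently initialized runs and keeps the one with the best validation
slice F1 — model selection on held-out slices only, never on test volumes.
Inference maps every slice's needle-probability map back to its position,
giving one probability volume per direction; the two are fused voxelwise by
**multiplicative averaging**, implemented as the geometric mean
√(p_lat·p_elev) — the multiplicative analogue of averaging,
threshold-equivalent to the raw product (also available). Fusion precedes
thresholding (`binarize`, default 0.5).

A `width_scale` knob multiplies every channel count (minimum 2) so the same
architecture trains on a CPU at desk scale; defaults (`width_scale=1`)
reproduce the full architecture.

## Axis estimation and the needle plane

RANSAC samples two distinct detected voxel centres per iteration (a line
determines the cylinder axis; the diameter is fixed, default 2.0 mm —
slightly above the largest clinical needle diameter), counts detected
centres within one radius of the infinite line, and keeps the largest
consensus (ties: first found; 1000 iterations fixed for determinism).
The winner is refined as the total-least-squares principal axis of its
inliers and the consensus recounted; refinement is toggleable. Fewer than
`min_inliers` (default 5) yields a distinguishable "no needle found" result
(`None`). The finite-segment constraint enters only at tip designation:
inlier centres are projected onto the axis, the endpoints are the extreme
projections, and the tip is the endpoint farther from the entry face (by
default the lateral/elevational volume face nearest to either endpoint).

The needle plane is spanned by the axis direction and the axial unit vector;
its normal is their normalized cross product, so the plane contains the
whole axis and is perpendicular to every coronal plane by construction. An
axis within 1e-6 rad of the axial direction is degenerate; the lateral–axial
plane through the axis point is returned, flagged. The in-plane view is
resampled trilinearly over the full volume footprint with zero fill, and the
axis/tip overlay is kept as a sidecar structure (never burned into the
image).

## Evaluation

* **Voxel metrics**: recall, precision, specificity and F1 from the voxel
  confusion matrix. With zero predicted positives, precision (and F1) are
  reported as missing — not zero — and excluded from fold averages, with the
  count of such folds logged.
* **Tip error ε_t**: point-plane distance from the ground-truth tip to the
  detected needle plane (what matters clinically: whether the tip appears in
  the displayed view).
* **Orientation error ε_v**: angle between detected and true axes in
  degrees, using the absolute dot product (axes are undirected; the sign
  convention of a fitted line is arbitrary).
* **Length-stratified curves**: phantoms are regenerated with the inserted
  length swept and all else fixed; means and standard errors of the mean of
  ε_t and ε_v are tabulated per length, and detector failures are recorded
  as missing rows rather than dropped.
* **Cross-validation**: volume-disjoint k-fold (default 5) with a hard
  error on any volume appearing in both train and test; fold metrics are
  averaged (mean ± std across folds), not voxel-pooled.

## Synthetic phantoms

The generator emulates the statistical structure of envelope-detected
B-mode needle volumes, not the physics of wave propagation:

* **Background**: a smooth low-frequency echogenicity field (coarse Gaussian
  random field, cubic-upsampled) multiplied by Rayleigh-distributed speckle
  with unit-mean scale, then lightly blurred (σ = 0.7 voxel). This yields
  the right-skewed intensity histogram and short-range spatial correlation
  characteristic of speckle.
* **Distractors**: randomly oriented bright tubes and ellipsoids whose
  intensity gains overlap the needle's, so detection cannot succeed on
  intensity alone.
* **Needle**: a straight cylinder of configurable diameter (0.72–1.47 mm
  clinical range) rasterized by exact point-to-segment distance; visible
  shaft voxels are brightened multiplicatively (`needle_intensity_gain`,
  default 5 — bright but inside the distractor gain range).
* **Dropout**: a configurable fraction of the shaft is rendered invisible
  in 1–3 *contiguous* runs along the axis (not i.i.d. voxels), mimicking
  beam-angle-dependent invisibility under steered phased-array acquisition.
  The ground-truth mask includes dropped voxels, as a human annotator labels
  the whole needle — so recall genuinely penalizes invisibility.
* **Shadow**: voxels deeper (along the axial/beam direction) than visible
  shaft are attenuated multiplicatively.
* **Pose**: the needle enters through a lateral or elevational face at a
  configurable steepness angle to the coronal plane (clinical settings span
  5–80° depending on transducer and tissue) and horizontal angle; the entry
  position is drawn uniformly among positions that keep the whole segment
  inside the volume, and a configuration whose needle cannot fit raises an
  error. Steepness angles are sampled uniformly over their stated range when
  a suite of phantoms is generated.

Default geometry follows the higher-resolution linear-array setting:
174×189×188 voxels at 0.2 mm, 17 G (1.47 mm) needle, up to 30 mm insertion.
All randomness flows through a numpy PCG64 generator seeded from the
config, making every phantom bit-reproducible.

What the phantoms do **not** model: anisotropic point-spread functions,
scan-conversion geometry of phased arrays, needle bevel/tip artifacts,
reverberation and comet-tail artifacts, tissue deformation, and curved
(deflected) needles. Passing tests on phantoms therefore demonstrate that
the pipeline's machinery — representation, training loop, fusion, geometry —
works end to end under controlled speckle-like statistics; they do not
certify ex-vivo or in-vivo performance.

## Desk-scale study sizes and numerical choices

The test suite and examples run on one CPU, so learned components train at
reduced scale as the package's own study design:

* ShareFCN learning checks: `width_scale` 0.0625, dropout off (the 0.85
  rate is calibrated for the full-width network and removes most of a tiny
  network's capacity), Adam step 1e-3 (suited to the much smaller parameter
  count), 3 epochs with the better of two restarts kept by validation slice
  F1, one rotation augmentation, eight training and two held-out 64³
  phantoms (0.2 mm voxels, 11 mm needles, gain 5, four distractors).
* Patch-CNN learning checks: filter widths (8, 12, 16, 24) and fully
  connected sizes (32, 16, 2) — the same topology at reduced width — on 48³
  phantoms, with harvesting and evaluation on stride-3 grids.
* The gap-sweep check compares `d` = 0 against `d` = 2.0 mm on phantoms
  with 35 % shaft dropout.

Other numerical decisions: He-normal weight initialization from each
model's own seeded generator; float32 arithmetic throughout the networks;
convolution via im2col and a single BLAS matmul; inputs to the FCN are
zero-padded on the bottom/right to multiples of 32 and outputs cropped
back; probability volumes are clipped to [0, 1] after fusion against
float rounding; RANSAC inlier tests use a 1e-12 mm slack so voxels exactly
on the cylinder surface count; cylinder rasterization includes centres at
exactly one radius (≤ r + 1e-9 mm).

## Known limitations

* Full-width (width_scale = 1) training is impractical on a single CPU;
  the defaults reproduce the architecture, not the training budget.
* The RANSAC iteration count is fixed rather than adaptive; for very large
  detection sets with many outliers the 2-point consensus may need more
  iterations than the default 1000.
* Straight needles only; a deflected-needle (parabolic) model is out of
  scope.
* The phantom's distractors are geometric primitives; real anatomy produces
  structured, connected false-positive candidates that are harder.
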