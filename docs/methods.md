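# Methods

## Problem setting and pipeline

A linear scar lies on a curved body surface; its clinically relevant length
is the 3D arc length of its centreline. The pipeline assumes:

- a triangle mesh of the skin surface in *model units* (photogrammetric
  reconstructions carry an arbitrary global scale),
- pinhole cameras registered in mesh coordinates (world→camera
  `x_cam = R x + t`, the COLMAP convention),
- per-view class maps for three classes: background, scar, and a circular
  fiducial sticker of known physical radius `r_true` (default 0.5 cm)
  placed on the skin near the scar.

Metric scale enters **only** through the fiducial: the measured skeleton
length `L_pc` (model units) is converted by `L_scar = L_pc / (2R) · 2r_true`
with `R` the apparent scale radius in model units. Every other step is
scale-equivariant, which the tests verify directly.

## Segmentation network and loss

The network is an encoder–decoder with two independent sigmoid output
channels (scar, scale); background is "neither channel above 0.5", and
pixels positive in both channels go to the larger probability. Binary
per-channel outputs keep the Dice and BCE losses in their plain binary form;
the joint loss is their sum, averaged over channels with equal weights, with
Dice smoothing `ε = 1.0` (the commonly used value; the loss is insensitive
to it away from empty masks, and `ε` in numerator and denominator makes the
empty-prediction/empty-truth case a correct zero).

Encoder: a 7×7/stride-2 stem **without maxpool** (slender structures
survive early downsampling better), then four residual stages of basic
blocks with strides 1, 2, 2, 2 — feature strides {2, 2, 4, 8, 16}. Decoder:
three blocks of (2× nearest upsample, concatenation with the
matching-stride encoder stage, two 3×3 conv-BN-ReLU), one block at stride 2
concatenating the stem feature (the fourth skip; no upsample is needed as
the strides already match), then a final 2× **bilinear** upsample and a 1×1
convolution. Bilinear interpolation at the final stage matters: a nearest
final upsample quantizes thresholded masks to 2×2 pixel blocks, which caps
the attainable boundary accuracy of thin structures.

`base_width` and `blocks` scale capacity; (64, (3,4,6,3)) reproduces the
ResNet-34 configuration, while the test suite trains (8, (1,1,1,1)) — on
flat-shaded synthetic imagery the task is colour discrimination plus
localisation, and the slim model reaches held-out Dice ≥ 0.95 in ~1 minute
of CPU time, which keeps the suite fast.

Training: SGD with momentum 0.9 and weight decay 1e-4, batch size 2, base
learning rate 0.01 under the per-iteration poly schedule
`lr = lr_base (1 − iter/total)^0.9`; augmentation is horizontal/vertical
flips and rotations uniform in ±30°, bilinear for images and
nearest-neighbour for masks (label integrity). A pretrained-encoder flag
exists for interface completeness but no weights are bundled and no test
depends on it. All layers (im2col convolution, batch normalization,
up-sampling, activations) are implemented in numpy with analytic backward
passes, verified against finite differences in the test suite.

## Remapping and fusion

A face receives one vote from a view iff its centroid projects inside the
image, the face is oriented toward the camera, and the centroid passes a
z-buffer test against the mesh's own depth rendering (relative tolerance
1e-2, since the centroid lies on the surface that generated the buffer; the
tolerance only needs to separate genuinely occluding sheets, which are far
apart on body-scale geometry). The vote is the mask label at the projected
pixel.

Fusion is per-face majority **among foreground votes**, ties broken
scar > scale; a face is background iff no view cast a foreground vote on
it. Background votes are tallied for diagnostics but do not compete:
counting them would let views added later strip a label established
earlier, violating the intended monotonicity of multi-view evidence
(a face visible and labelled in one view stays labelled).

## Sampling and class extraction

Point sampling is area-weighted over faces with uniform barycentric
placement (`n = round(density · area)` points). Each point inherits its
face's label and class colour. Class extraction by colour uses a dominance
rule — scar iff `r > 2·max(g,b)` and `r > 60/255`, scale symmetrically in
green — exact on the pure-colour encoding and tolerant to moderate blending;
black background never passes. Outlier removal is the standard k-NN
statistical filter (k = 20, α = 2): drop points whose mean distance to
their 20 nearest neighbours exceeds the global mean + 2 std of that
statistic. On outlier-free clouds it removes only boundary points (~a few
percent on a convex hull boundary; ≥ 99.9% of interior points survive).

## Skeleton, scale radius, calibration

Skeleton: the main direction is the coordinate axis of largest span (ties
X > Y > Z), relabelled X with the minimum shifted to 0. The range
[0, X_range] is partitioned into `M = floor(X_range/(R/10))` half-open
windows of width `R/10` (the last window closed); each non-empty window
contributes the mean of its points. The polyline length over the ordered
skeleton points is `L_pc`. The window width is tied to the apparent scale
radius `R`, making the resolution adapt to the reconstruction's scale.
The skeleton assumes one monotone main direction — scars that double back
along every coordinate axis are outside the method's domain.

Scale radius: centre = scale-cloud centroid; points are projected onto the
plane of the two leading principal axes; the farthest point in each of 72
polar-angle bins forms the edge set, and `R` is the median edge distance.
Binning makes the edge set density-independent; the median resists residual
mislabelled points.

Repetition: sampling is random, so the measurement repeats (default 10×)
with sub-seeds spawned from one seed, and the reported length is the mean;
per-repeat values are kept for inspection.

`measure_scar` samples only the scar+scale submesh — background faces
contribute nothing to either quantity — which keeps the cost proportional
to the labelled area rather than the whole surface.

## Synthetic scenes: what they emulate, and their resolution requirements

The generator re-creates the validation design of the physical simulation
experiment: artificial scars of known length drawn at true scale and
attached to curved surfaces. A scar is a constant-width stroke (default
0.3 cm) swept along a parametric curve in surface (u, v) coordinates; the
surface parametrizations are chosen (near-)isometric — cylinder arc-length,
sphere exponential map, shallow paraboloid — so drawn sizes survive onto
the curved surface the way printed paper wrapped on an object does. Ground
truth `L_true` is the centreline's 3D arc length by refined polyline
integration (successive halvings to 1e-6 relative agreement); stroke ends
are cut square (butt caps), so the painted stroke length equals `L_true`.

Meshes are expressed in model units at `units_per_cm = 5` (one unit =
2 mm), a realistic photogrammetric scale: with the stated density of 1000
points per square model unit this yields ~270 points per angular bin on the
disk edge and ~380 per skeleton window, putting the sampling-noise terms of
both estimators well below 1%. (With one unit = 1 cm the same density gives
~11 per bin and ~15 per window, and the bin-maximum and window-mean
statistics are then dominated by sampling noise — several percent of
systematic bias. The density is a per-model-unit quantity; it only has
physical meaning jointly with the reconstruction scale.)

Tessellation (0.1 cm cells) is refined locally: ×4 near the disk boundary
(the bin-max edge estimator reads the boundary's face quantization
directly) and ×2 along the scar band (staircased edges of a sloped stroke
otherwise inject deterministic window-mean jitter that inflates the
polyline length by a few percent). Rendering is flat-shaded with exact
class colours and no lighting — a deliberately controlled baseline; optional
Gaussian pixel noise and colour jitter exist for robustness experiments.

The five standard scenes span scar lengths ~1.4 / 6.8 / 10.5 / 12.7 /
20 cm on a plane, two cylinder patches (radii 8 and 6 cm), a sphere patch
(radius 12 cm) and a shallow paraboloid. The original experiment's surface
shapes are not documented; these curvatures are this package's choice of a
skin-like range, and the lengths approximate the published set.

What passing synthetic tests does **not** show: robustness to real
photographic appearance (texture, lighting, specularity, blur),
reconstruction error in the mesh or camera poses, or clinical scar
appearance — the synthetic path validates the *geometry* of remapping,
sampling, skeletonization and calibration, and the *mechanics* of training,
not clinical segmentation accuracy.

## Numerical choices and degenerate inputs

- Pixels are 0-based with integer centres; rasterization interpolates depth
  perspective-correctly (1/z linear in screen space); masks and images are
  rendered with the identical projection, so they are aligned by
  construction.
- Determinism: scene generation, rendering, sampling (per-seed), the
  measurement (seed + spawned sub-seeds) and the pipeline report are
  deterministic; `report.json` contains no timings (they go to a sidecar),
  so repeated runs are byte-identical.
- Undefined ratios (sensitivity with an absent class, correlation of a
  constant series, std of one value) are returned as NaN, never silently 0.
- Degenerate inputs raise: empty clouds, zero-span skeletons, collinear
  scale clouds, zero reference lengths, meshes with zero area. Clouds
  smaller than k+2 skip outlier removal with a warning.
- Error summaries use the sample standard deviation (n−1), which is the
  convention that reproduces the published clinical summary row exactly.
- Bland–Altman differences are automatic − manual; limits are
  bias ± 1.96·SD (sample SD).

## Known limitations

- Single scar and single scale per scene; branched, closed, or
  strongly-retrograde scars violate the skeleton's monotone-direction
  assumption.
- Per-face (not per-texel) remapping: scars thinner than a mesh face cannot
  be resolved; the synthetic meshes are refined so faces are well below the
  stroke width.
- The fiducial is assumed rigid and flat against the skin; strong sticker
  deformation biases `R` and hence the calibrated length.
- The SfM/MVS reconstruction itself is out of scope: the pipeline consumes
  its outputs and inherits its errors.
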