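# scarmetry

Automatic, non-contact measurement of **linear skin scar length** from
multiview photographs, for forensic and clinical use. Manual scar
measurement with rulers or flexible wire requires touching the subject and
is subject to observer variation; 2D image measurements ignore that scars
lie on curved body surfaces. scarmetry measures scars **in 3D**: a surface
mesh reconstructed from ordinary photographs (by external photogrammetry
software such as COLMAP/OpenMVS), a CNN that segments the scar and a
circular fiducial scale in each view, remapping of the 2D segmentations onto
the 3D surface, and a point-cloud skeleton measurement calibrated by the
scale's known radius.

## Method

Given a reconstructed surface mesh, registered pinhole cameras, and per-view
segmentation maps (scar / scale / background):

1. **Segmentation** — an encoder–decoder network (ResNet-34-style encoder
   with the stem maxpool removed, four skip-connected decoder blocks, two
   sigmoid output channels) trained with the joint loss

   L_total = L_Dice + L_BCE,
   L_Dice = 1 − (2 Σᵢ pᵢgᵢ + ε) / (Σᵢ pᵢ² + Σᵢ gᵢ² + ε),
   L_BCE = −(1/N) Σᵢ [gᵢ log pᵢ + (1−gᵢ) log(1−pᵢ)],

   with SGD (momentum 0.9, weight decay 1e-4) and the poly schedule
   lr = lr_base · (1 − iter/total_iter)^0.9.
2. **Remapping** — each face of the mesh is voted on by every view in which
   its centroid is visible (frustum + facing + z-buffer test); votes are
   fused by per-face majority among foreground classes.
3. **Sampling** — the labelled mesh is sampled to a point cloud
   (area-weighted, 1000 points per square model unit); per-class clouds are
   extracted by colour thresholding and denoised by a k-NN statistical
   outlier filter.
4. **Skeleton & length** — the scar cloud's main direction (largest
   coordinate span) is relabelled X; the X-range is split into windows of
   width R/10, where R is the apparent scale radius, and each non-empty
   window yields one skeleton point P_m = mean(Pᵢ, xᵢ ∈ w_m). The skeleton's
   polyline length L_pc is calibrated through the scale of true radius
   r = 0.5 cm:

   L_scar = L_pc / (2R) (cm).

   R is the median distance from the scale-cloud centroid to its
   per-angular-bin edge points. Because sampling is random, the measurement
   is repeated (default 10×) and averaged.

A synthetic-scene generator provides ground truth: curved surface patches
(plane, cylinder, sphere, paraboloid) carrying a scar stroke of analytically
known arc length and the 0.5 cm disk, rendered to multiview images with
pixel-aligned masks by a built-in z-buffer rasterizer.

## Worked example

Measure a short scar (~1.41 cm true arc length) on a sphere patch through
the full synthetic pipeline:

```bash
cat > pipeline.json <<'EOF'
{"mode": "synthetic", "scene": "scar3", "repeats": 10, "density": 1000.0, "seed": 7}
EOF
scarmetry run --config pipeline.json --out run_scar3
```

prints

```
L_scar = 1.3733 cm (reference 1.4077 cm, RE 2.44%)
```

i.e. the calibrated skeleton length averaged over 10 resamplings is
1.3733 cm against the analytic ground truth 1.4077 cm — a relative error of
2.44%, inside the < 5% regime this approach is validated to. The run
directory contains `report.json` (measurement, per-repeat values, config),
the labelled point cloud and the skeleton as PLY for visual inspection.

Summarise the bundled table of 30 published clinical measurement pairs
(automatic vs forensic-expert manual):

```bash
scarmetry evaluate --out summary.json
# RE 3.69 +/- 2.35% (max 7.22, min 0.11); summary at summary.json
```

Other CLI verbs: `simulate` (write a synthetic scene, its views, masks and
cameras), `train`, `segment`, `remap`, `measure` — each stage runnable on
its own artifacts.

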