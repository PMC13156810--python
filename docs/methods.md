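# Methods

This note documents the models, numerical choices and limitations of the
package: the synthetic phantom, the preprocessing and ROI-inflation rules,
the two networks and their training schedule, the geometric stenosis
measurement, and the evaluation statistics. Parameter defaults are stated
with units and rationale; everything listed is configurable through the
`preprocess` / `locnet` / `segnet` / `train` / `stenosis` / `metrics` /
`phantom` blocks of the YAML config.

## Synthetic phantom

`caroseg.phantom` emulates the statistical and geometric regime of
black-blood (dark-lumen) T1-weighted neck MRI, not its physics. One
phantom is a Y-shaped tube tree: the common carotid (CCA, default radius
3.0 mm) runs along the slice axis and bifurcates into internal (ICA,
2.4 mm) and external (ECA, 1.8 mm) branches splayed symmetrically in-plane
(default total angle 50°), each branch 50 mm long at full scale. These
radii and the bifurcation angle are ordinary adult values from the
clinical literature; the study underlying the design reports no geometry
statistics of its own, so the defaults are engineering choices.

A focal stenosis on a branch multiplies the radius by
`1 − (p/100)·½(1 + cos 2πu)` for `|u| = |s − c|/L ≤ ½` — a raised-cosine
taper from full radius to `(1 − p/100)·r` at the throat. It is smooth,
differentiable, and preserves the analytic throat, so every phantom
carries exact ground truth (true MLD, RVD, NASCET percent, throat
position, centerline).

Voxelization uses the pixel-center-in-tube rule, implemented as a union of
balls along the centerline sampled every quarter voxel (sub-voxel accurate
for smooth radius profiles). The image is a three-level intensity model —
background 100, wall ring 180 (1 mm thick), lumen 30 a.u., i.e. a dark
lumen in a bright wall as in VISTA/SPACE/CUBE sequences; polarity is
configurable through the three intensities — plus seeded Gaussian noise
(default SD 8, ≈11% of the background level). Identical specs give
bit-identical volumes.

The default full-size grid (192×352×352 voxels at 0.59×0.46×0.46 mm)
yields a labeled-lumen fraction of ≈0.099% of the grid, reproducing by
construction the sub-0.1% artery occupancy that makes carotid
segmentation hard.

Cohorts (`generate_cohort`) draw one ICA stenosis per lesion with the
NASCET percent sampled inside its grade's band (mild 10–28, moderate
33–67, severe 72–92 — kept away from the 30/70 boundaries so a cohort
lesion's true grade is well defined at voxel tolerance), jitter radii and
angle by ±10%, assign a scanner-style spacing tag, and stratify grades by
largest-remainder rounding; the default mix is 3:206:336, the
training-validation stratification of the multicenter cohort the pipeline
is designed around. One artery tree per volume; bilateral anatomy is out
of scope.

What the phantom does *not* model: MR physics (coil sensitivity, flow
artifacts, partial-volume blur beyond voxelization), plaque components,
vessel-wall (outer-wall) labels, neighboring anatomy (jugular vein,
vertebral arteries), and real lesion-shape statistics. Passing tests on
phantoms therefore demonstrate the correctness and internal consistency of
the pipeline — containment of the cascade, metric definitions, geometric
measurement accuracy at known truth — not clinical performance on patient
data.

## Preprocessing and the ROI target

Volumes are resampled to a common spacing (default 0.59×0.46×0.46 mm;
images trilinear, labels by interpolating the binary indicator and taking
its 0.5 level set, which keeps the output binary while tracking the
surface with sub-voxel accuracy — plain nearest-neighbor inflates a
3-mm tube's volume by ~18% on a down/up round trip) and z-score
normalized with the population SD (constant volumes map to zero).

The localization target inflates each slice's label: with N labeled
pixels of size l×w mm², the disk of radius `(1+ε)·√(l·w·N/π)` about the
label centroid is united with the label (union, never replacement — a
coverage guarantee; slices without labels stay empty). ε defaults to 0.5:
a generous margin around the artery while keeping the ROI small. The disk
is rasterized with the same pixel-center rule as the phantom. The
equivalent-circle reading of the inflation radius is the only
dimensionally consistent one (it has units of length and reduces to the
disk radius when the label is a disk and ε = 0).

Augmentation covers in-plane rotation (±30°), isotropic scaling
(0.7–1.4), per-axis flips (p = 0.5), additive Gaussian noise, Gaussian
smoothing (σ 0.5–1 voxel), intensity scaling (0.75–1.25) and gamma
contrast (0.7–1.5); spatial transforms are applied identically to image
and label (label nearest), intensity transforms to the image only, all
seeded. The transform families are standard volumetric-segmentation
practice; the ranges are defaults, not fitted values.

## Networks and training

Both networks are U-Nets built from two convolution(+instance norm+leaky
ReLU, slope 0.01) blocks per stage with skip connections, strided-conv
downsampling, transposed-conv upsampling, base 32 channels doubling to a
320 cap, and a single sigmoid output channel:

* **Localization (2D)**: 8 encoder / 7 decoder stages at full scale;
  inputs are padded to divisibility by 2⁷ and un-padded after inference.
* **Segmentation (3D)**: 6 encoder / 5 decoder stages with residual
  encoder blocks (identity shortcut, 1×1×1 convolution when channels or
  resolution change). Encoder stages 2–3 (0-based 1–2) downsample by
  average pooling in their first block, deeper stages by strided
  convolution; which stages pool is configurable since the reference
  design leaves it open.

Training uses SGD with Nesterov momentum 0.99, initial learning rate 0.01
under polynomial decay `lr(e) = 0.01·(1 − e/E)^0.9`, batch sizes 12 (2D)
and 4 (3D), 1000 epochs at full scale, a 1:1 binary cross-entropy +
soft-Dice loss, and deep supervision: auxiliary heads at up to the three
finest decoder resolutions, per-level weights halving with depth and
normalized to one, targets downsampled by block maximum (which keeps thin
vessels present at coarse scales). Gradients are clipped to a global norm
of 12. The 3D stage sees four random 128×192×192 patches per ROI per
epoch at full scale, corners uniform, zero-padded when the crop is
smaller than the patch.

The two stages are trained sequentially (localizer first, segmenter on its
frozen crops); per-fold localizers and segmenters are trained within
five-fold cross-validation stratified by grade (and scanner tag when
present, degrading with a warning when a class has fewer members than
folds). Inference averages the fold models' probability maps and
thresholds at 0.5 ("fold ensembling"); a largest-component post-filter is
available but off by default. The ROI crop is the union bounding box of
the slice-wise predictions expanded by an 8-voxel margin; an empty
prediction raises an explicit no-ROI-found error (callers may fall back to
the full volume).

The engine itself (`caroseg.nn`) is a compact CPU implementation with
explicit forward/backward passes — im2col convolutions dispatched to BLAS,
the input gradient computed as a dilated flipped-kernel correlation —
verified against finite differences in the test suite.

### Desk profile

The `desk` profile is the package's own scaled-down experimental
condition so the complete cascade trains on one CPU in minutes: phantoms
of 48×72×72 voxels at 1.0×0.8×0.8 mm with 16-mm branches; a 4-stage,
8-base-channel localizer trained 6 epochs at batch 4 on every third
slice; a 4-stage, 8-base-channel residual segmenter trained 24 epochs on
two 16³ patches per lesion at batch 4. On a seeded 12-phantom cohort this
reaches fold-ensemble Dice ≳0.9 against ground truth, and the
no-localization ablation — identical patch budget drawn from whole
volumes, where most patches contain no artery — trains visibly worse,
reproducing the qualitative value of the localization stage. The
full-scale printed performance of the reference study is not reproducible
here: its multicenter image data are not public.

## Stenosis quantification

* **Centerline**: shortest paths through the 26-connected lumen voxel
  graph with edge costs `step length × mean of 1/(d + ε)²` over the edge's
  endpoints, where d is the Euclidean distance transform (mm) — paths hug
  the medial axis (the classical penalized-distance centerline, in the
  spirit of VMTK's geometric centerlines). The main path joins the two
  geodesically farthest tips; the longest side path (≥5 mm) attaches at
  the bifurcation. Open tips are trimmed by about two local radii (end
  caps carry no medial signal), each point is recentred to the centroid of
  its perpendicular cross-section (two passes), and paths are smoothed
  with a short moving average. A mask without a qualifying side branch
  degenerates to single-branch mode. 3D thinning was rejected as the
  primitive here: the standard implementation deletes perfectly
  symmetric even-width tubes outright.
* **Branch labels**: the CCA is the arm heading inferior from the
  bifurcation (largest median radius as tie-break); of the two distal
  arms the ICA is the one with the larger median radius (radii from the
  distance transform, junction zone excluded).
* **Straightening**: cross-sections sampled every 0.25 mm perpendicular
  to the centerline tangent on a 64×64 plane at 0.15 mm pitch, with a
  parallel-transported in-plane frame (no torsion flips). The binary mask
  is interpolated linearly and thresholded at 0.5 — the 0.5 level set of
  the indicator tracks the true surface with sub-voxel accuracy, where
  nearest-neighbor lookup acts as a Voronoi dilation and over-measures
  thin throats by ~25% in diameter. Each plane keeps only the connected
  component around the centerline point, so planes near the bifurcation do
  not double-count the neighboring branch. If the lumen touches the plane
  border the plane is enlarged once, with a warning.
* **Profile and diameters**: per-plane area = foreground pixels × pixel
  area (mm²), box-smoothed over 3 planes (0.75 mm); equivalent diameter
  `d = 2√(A/π)` reconciles the diameter-based NASCET definition with
  area profiles and is rotation-invariant.
* **MLD**: minimum of the smoothed ICA profile, excluding 2 mm distal to
  the bifurcation (flow-divider artifact) and 2 mm at the distal end;
  ties resolve to the most proximal plane.
* **RVD**: default `distal_ica` — the median equivalent diameter of the
  ICA beyond the MLD plane plus a 5-mm recovery zone (falling back to the
  guarded-ICA median when that window is empty). This is the NASCET
  denominator (normal distal ICA). The alternative `bulb_max` — the
  maximum diameter within 10 mm of the bifurcation, i.e. the dilated
  carotid bulb — is selectable; the two conventions genuinely disagree
  and neither is asserted as the only valid reading.
* **Grading**: mild (0, 30], moderate (30, 70], severe (70, 100), closed
  upper boundaries; two-class merge pools mild+moderate as non-severe.
  Percent 0 and 100 (occlusion) are outside the graded range — occluded
  arteries are an exclusion criterion of the underlying study design.

Measurement resolution: a 90% stenosis of a 2.4-mm-radius ICA has a
0.24-mm throat radius — thinner than typical in-plane voxels. The
parameter-recovery suite therefore voxelizes its phantoms at
0.4×0.25×0.25 mm, where a covering-radius argument guarantees the throat
always contains at least one voxel center, and samples planes at 0.15 mm
so no sub-voxel blob is missed. Under those conditions recovery across
target percents 20–90 with ±10% geometric jitter is within ±2 points
(the suite's bound is ±5). At the study's native 0.46 mm spacing severe
throats are at or below one voxel and the percent estimate saturates —
an intrinsic limit of mask-based measurement, not of the algorithm.

## Evaluation statistics

Overlap: Dice `2|P∩T|/(|P|+|T|)`, IoU, absolute relative volume error
`||P|−|T||/|T|`, voxel sensitivity, and specificity (computed on the ROI
crop by default — on a whole volume the background dominance pins it at
1). Surfaces: boundary voxels by 6-connectivity face exposure, distances
in mm between boundary voxel centers; ASSD is the mean and HD95 the 95th
percentile of the pooled symmetric distance multiset. These definitional
choices are standard and are verified exactly against an all-pairs
brute-force oracle in the tests.

Diagnostics treat each artery as a subject of the two-class severe /
non-severe task: accuracy, F1, sensitivity, precision, specificity from
the 2×2 table, AUC as the rank statistic over a continuous score (the
NASCET percent). Agreement: Lin's concordance correlation coefficient
(population variances) with a Fisher-z confidence interval, and ICC(2,1)
(two-way random effects, absolute agreement, single measure) with the
Shrout–Fleiss F-based interval. Paired comparisons use the Wilcoxon
signed-rank test: zero differences dropped, midranks for ties, exact
null distribution by subset-sum dynamic programming for n ≤ 25 and the
tie-corrected normal approximation otherwise; α = 0.05.

## Known limitations

* The phantom's realism limits are listed above; in particular the
  desk-scale training results say nothing quantitative about patient
  data.
* The numpy engine is single-threaded BLAS-bound; the full-scale `paper`
  profile (1000 epochs, 128×192×192 patches) is expressed but not
  practical to run on CPU.
* The reference architecture's undisclosed layer details (normalization,
  activation, exact pooling placement, deep-supervision weights) are
  filled with common U-Net practice and are configurable.
* Quantification assumes a single Y-bifurcation; more complex trees
  (e.g. proximal ECA branches) would need branch-labeling extensions.
* DICOM ingestion, ECST/area-based stenosis indices, plaque and
  vessel-wall analysis are out of scope.
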