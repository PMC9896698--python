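# Methods

`root3d` quantifies the 3D architecture of excavated, mesh-supported root
systems from dense photogrammetric point clouds. This note documents the
models and estimators behind each stage, the parameters that matter, what
the synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Input model and preprocessing

The input is a *surface* point cloud in an arbitrary similarity frame:
multi-view stereo reconstructs the visible surface of the root system, the
black support mesh, and sparse outliers. Preprocessing maps this to the
canonical metric frame (cm; plant base at the top, growth along −z):

- **Color-based mesh removal.** Points within a Euclidean RGB distance
  (default threshold 40 on the 0–255 scale) of a reference color are
  deleted. The matte-black mesh and lit root tissue are widely separated in
  RGB, so the exact threshold is uncritical over a broad range.
- **Statistical outlier removal.** The classical k-nearest-neighbor rule:
  a point is removed when its mean distance to its k nearest neighbors
  (default k = 10) exceeds the global mean by more than n_std standard
  deviations (default 2.0). Reflection artifacts that form locally dense
  clusters are *not* removed by this rule; that is a known limitation
  inherited from the filtering model.
- **Scaling and orientation.** Two reference points with a known separation
  (e.g. a support-mesh disc of known diameter) fix the scale; a user-supplied
  up vector fixes the orientation via the minimal rotation taking it to +z
  (the antiparallel case resolves to a 180° rotation about x). Both
  operations are rigid/similarity transforms; all cleaning operations return
  order-preserving subsets of their input.
- **Surface-noise estimate.** The sensor jitter σ is estimated from the
  cloud itself: local planes are fit by PCA over 12-point neighborhoods at
  up to 4000 sampled points, and σ̂ is the median out-of-plane standard
  deviation. σ̂ feeds the diameter corrections below. On generated clouds
  with known jitter the estimator recovers σ within ~20% (it slightly
  underestimates on curved surfaces, which is benign at these magnitudes).

## Voxelization and the cell-size criteria

A voxel is on iff at least one point falls inside it (half-open cells). The
cell size trades fragmentation against merging; the diagnostic mirrors the
visual criteria with countable proxies per candidate size: 26-connected
component count (continuity), interior-cavity count (holes in thick roots;
background components not connected to the exterior under 6-connectivity),
and the on-voxel ratio against the finest candidate (merging/thickening
proxy). The recommended size is the smallest candidate with zero cavities
and a component count within 1.5× of the coarsest candidate's; the user can
always override it. The default cell size is 0.1 cm and grids are capped at
1e9 cells.

Because the input samples only surfaces, thick roots voxelize into hollow
shells, and a hollow tube skeletonizes into a medial *surface*, not a
centerline. An explicit cavity-filling step therefore implements the
"continuous root without holes" criterion computationally: every z-slice is
2D-filled first (robust to isolated pinholes in the sampled wall), then any
remaining sealed 3D pockets are filled volumetrically. All downstream
analysis runs on the filled solid.

## Global traits

- **Depth** = vertical extent of the cloud; **width** = maximum pairwise
  distance of the horizontal projection, computed exactly via the 2D convex
  hull plus rotating calipers (the projection of a root system is often
  nearly co-circular, so all points can be hull vertices).
- **Convex hull volume** via Qhull (quickhull).
- **Volume** = on-voxel count × cell³ (the raw count estimator).
- **Surface area** = exposed voxel faces × cell². Voxel face counting
  inflates smooth oblique surfaces by up to ~1.5× (staircase effect); the
  estimator is validated against analytic shapes with that bound and the
  bias is documented rather than hidden.
- **Skeleton** by 3D homotopic thinning (Lee's method as shipped in
  scikit-image), which preserves 26-connected components and cycle rank.
  The skeleton voxels form a graph with 26-adjacency edges of length
  cell × {1, √2, √3}; **total root length (TRL)** is the sum over a
  per-component minimum spanning structure of that graph, so parallel
  adjacencies around junctions are never double counted. On straight axis or
  diagonal runs this is exact. On oblique runs the local weights
  overestimate length by up to ~8%; TRL keeps the classical estimator (its
  bias is consistent, which is what the depth/width/TRL regressions need),
  while the local traits below use chord-subsampled path lengths instead.
- **Average diameter** via the cylinder identities SA/(π·TRL) or
  2√(V/(π·TRL)) (default). The volume fed to the formula is
  dilation-corrected, see below.

### Occupancy dilation and the diameter corrections

A voxel solid built from a surface cloud is the true solid dilated by
roughly half a cell plus the sensor jitter: measured on cylinder phantoms
(radii 0.10–0.75 cm, cell 0.1 cm, jitter 0–0.03 cm) the radius excess is
δ ≈ 0.5·cell + 1.4·σ, nearly independent of radius. Raw count volume would
therefore inflate a thin-root diameter by tens of percent. Wherever a
diameter is computed, the package inverts the cylinder identity and removes
δ: r̂ = √(V_on/(π·L)) − δ with δ = 0.5·cell + 1.4·σ̂. The 1.4 factor is a
calibration constant measured once on the phantom battery; after the
correction, phantom diameters are recovered within ~±3% across the radius
range.

## Root length density

Every spanning edge contributes its full length to exactly one bin, chosen
by the edge midpoint: the cube containing it (cubes anchored at the stem
base; default cube volume 3 cm³, i.e. edge ≈ 1.442 cm — a cube *edge* of
3 cm is available via configuration), the depth bin below the base, or the
radial bin around the vertical axis through the base (default bin 5 cm for
both profiles). Midpoint assignment makes all three outputs conserve TRL
exactly (to float summation order, ≪1e-9 relative), which is asserted per
run. The base defaults to the highest skeleton voxel.

## Main/lateral segmentation

The filled voxel model is sliced top to bottom and the main root/stem is
tracked one layer at a time:

1. **Seed.** The topmost slice whose largest 8-connected component is at
   least 30% of the largest component seen in the top ten non-blank slices
   (plain "topmost non-blank" is not robust: isolated jitter specks above
   the root base would seed the tracking).
2. **Search region.** The previous main mask is unit-dilated until its area
   has grown by 10% (one extra dilation per missed layer to allow drift).
3. **Opening.** Within the search region, a morphological opening with a
   disc of radius r₀ = round(0.5 · equivalent radius of the previous main
   mask) removes thin lateral cross-sections; the radius escalates to 2·r₀
   while more than one component survives. When the upstream main is thin
   (r₀ = 0) no opening is applied — a 2-px-wide taproot tip would not
   survive any disc. The component continuing the main is the one with the
   largest overlap with the previous mask (nearest centroid as tiebreak).
   Its 1-px ragged boundary ring (jitter fuzz shaved by the erosion) is
   re-adsorbed, except where the residue survives a unit opening and is
   therefore a genuine lateral.
4. **Termination and gaps.** Fully blank layers (support-mesh fractures),
   layers with an empty search region, and layers where nothing survives
   opening are carried for up to max_carry_layers (default 10). A candidate
   resuming after missed layers must pass a continuity check (area ≥ 30% of
   the last mask, centroid within 1.5 equivalent radii) so a lateral blob
   drifting into the widened search region cannot hijack the main. If the
   grace run is exhausted the main is declared terminated and all deeper
   voxels are lateral — this is what stops a maize stem at its base.
5. **Scrubbing.** Thin lateral shell fragments hugging the main surface
   (within 2 voxels of MAIN and 3 layers of its span, failing a unit 3D
   opening) are dropped from both classes. They are occupancy dilation fuzz
   with no root of their own; left in place they decorate lateral skeletons
   with phantom arcs worth ~20% of branch length. Their count is recorded
   (`RootLabels.n_scrubbed`), so the label partition
   MAIN ∪ LATERAL = on-voxels ∪ bridged holds up to that recorded set.

**Bridging.** Runs of at most max_gap_layers (default 5 ≈ 0.5 cm) blank
MAIN layers flanked by non-empty MAIN are filled with discs interpolating
the flanking centroids and equivalent radii; filled voxels carry a bridged
flag. Longer gaps stay open with a warning naming the layer range.

Known limitations, by construction: segmentation quality degrades as the
lateral caliber approaches the main's (the opening can no longer separate
them — verified as a monotone precision decline in the tests), and a main
root with rapid horizontal bends can outrun the search region.

## Local traits

- **Main length** is measured on the polyline through the per-slice MAIN
  centroids (lightly smoothed, window 3), plus half a cell per end cap,
  minus the end dilation 2δ. A skeleton longest-path length is *not* used:
  homotopic thinning of a thick flat-capped stem leaves medial plates whose
  rim inflates a path length by >20%, while the centroid axis is exact on
  phantoms and matches the slice-tracking model.
- **Main diameter** comes from per-slice equivalent radii measured only on
  junction-free slices (no lateral voxel within 2 px of the MAIN mask in
  that slice or its ±4 neighbors); radii on junction slices are linearly
  interpolated from clean flanks and bounded above by the measured value
  (collars only ever add area). Each radius is reduced by δ; the diameter
  then follows 2√(V/(π·L)).
- **Lateral skeletons** are cut at branch points (skeleton voxels with ≥3
  neighbors in 26-adjacency, adjacent junction voxels merged) into ordered
  simple paths; 26-connected debris components below 20 voxels and segments
  shorter than 0.5 cm are discarded as sensor debris.
- **Emerging segments** (= countable roots) must approach the main skeleton
  closer than the maximum main diameter (max over slices of the equivalent
  circle diameter) *and* recede from it: the far end must stand at least
  half that diameter farther out than the near end. The second condition
  rejects junction-collar arcs that hug the main at both ends. Reported
  branch lengths run from the insertion on the main axis: the start gap
  (start point to main skeleton) and the far-end thinning retraction
  (marched from the path end along its tangent through the mask) are added.
- **Branch mean diameter** uses the lateral-class support length (segment
  paths plus both retraction extensions, without the buried insertion run)
  as the denominator, matching the voxel volume's support.
- **Initial angle** is the angle between the downward vertical and the
  chord from the path voxel 10 steps from the start point to the voxel 20
  steps away (defaults; a plumb-vertical root scores 0°). The first ~10
  voxels are excluded because the skeleton of a cut lateral hooks along the
  main-root surface there, biasing start-anchored vectors by 5–8° toward
  the vertical; `offset_hi=None` restores the literal start-to-offset
  vector. Short paths fall back to their far end and are flagged. Angle
  summary statistics report mean, SD, and CV = SD/mean × 100.

## The synthetic generator

Centerlines are piecewise-linear curves built before discretization, so all
ground truth is exact by construction: the main axis is vertical with
sinusoidal wander (default amplitude 0.5 cm, wavelength 30 cm) and linear
radius taper; branches leave at a prescribed polar angle (golden-angle
azimuths) and optionally curve toward −z at a constant rate (gravitropism;
rate 0 gives straight roots for exact angle tests). Tube surfaces are
Poisson-sampled at 800 points/cm² (≈0.35 mm spacing, a typical
close-range-photogrammetry density), with flat end caps, Gaussian jitter
(default σ = 0.015 cm), uniform box outliers (0.5%), optional near-black
mesh-point clusters at 12 cm vertical spacing, and optional blank slabs
simulating mesh-removal fractures. Every point carries a provenance label
(main / branch / outlier / mesh), and voxel-level truth labels are derived
by testing voxel centers against the analytic tubes (margin: half a voxel
diagonal).

Two presets define the study conditions. *Taproot* (rapeseed-like): main
radius 0.45→0.10 cm, six laterals of radius 0.16 cm (~36% of the main) at
55 ± 8° inserted over the top 8–60% of the axis, lengths 0.30–0.45× the
main depth. *Fibrous* (maize-like): below-ground stem of length
clip(0.2 × system depth, 4–8 cm) and radius 0.80→0.70 cm, bearing
unbranched nodal roots of radius 0.30 cm (40%) at 40 ± 8°; the visible
nodal count grows with plant size from 6 to 12, mirroring how nodal roots
accumulate over growth stages. The validation cohort spans five size
stages per architecture (taproot depths 12–60 cm, fibrous system depths
10–38 cm), three replicates each.

What the generator does *not* emulate — and hence what passing recovery
tests do not certify on real data: occlusion and missing surface patches in
dense crowns, second-order laterals, reflection artifacts with locally
dense structure, non-Gaussian reconstruction error, root clumps with soil
residue, and main roots with sharp horizontal bends.

## Numerical choices and degenerate inputs

Half-open voxel assignment uses a 1e-9 cell epsilon so exact-boundary
coordinates land deterministically. Coincident clouds yield zero depth and
width with a warning and an undefined (NaN) width/depth ratio; coplanar
clouds yield zero hull volume with a warning; TRL = 0 makes the diameter
NaN. Ties in component selection during tracking resolve to the largest
component. Every stage is deterministic: identical inputs and parameters
give identical outputs, and the generator is byte-reproducible from its
seed.

## Validation summary

The test suite checks the estimators against closed forms (hull volumes,
voxel areas, chamfer lengths), Monte-Carlo oracles (ball hull volume),
topology oracles (component count and cycle rank on bar/Y/torus phantoms),
exact conservation of TRL across the density outputs, and parameter
recovery on the synthetic cohort: pooled relative RMSE of main length and
diameter ≤5%, of lateral length/diameter/angle ≤7%, voxel-level main-root
precision and recall ≥0.9, and extracted-vs-true r² ≥ 0.9 for depth, width
and TRL. `scripts/acceptance.py` recomputes the cohort metrics end to end.
Problem sizes (30 specimens, cell 0.1 cm, up to ~1.3e8-cell grids) keep a
full validation run within a few minutes on one CPU.
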