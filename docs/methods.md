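# Methods

This note documents the models and procedures implemented in `tauscape`,
their assumptions, the parameters that matter, and the design choices made
where the published workflow leaves the design open.

## Coordinate and intensity conventions

Volumes are `(z, y, x)` arrays with per-axis voxel pitch in micrometres.
The physical coordinate of voxel `i` is `(i + 0.5) × pitch` (voxel-centre
convention), so a single-voxel spot's centroid lies at the voxel centre and
assignment back to a voxel is `floor(coordinate / pitch)`.  Intensities are
arbitrary fluorescence units, held as float64 regardless of on-disk type.
Supported volume formats are multi-page TIFF (pitch stored as a JSON
description tag) and NRRD; tables travel as CSV.

## Tau deposit extraction

1. **Resampling.**  Acquisitions at 6.5 × 6.5 × 8.3 µm are trilinearly
   resampled to the isotropic standard pitch (default 8.3 µm) on the
   voxel-centre lattice; sample points outside the source lattice clamp to
   the nearest face.  An already-isotropic volume passes through untouched.
2. **Band-pass.**  The deposit signal is amplified by subtracting a large
   mean filter from a small Gaussian: `G_σ(I) − M_w(I)` with σ = 0.83
   voxels (FWHM = 2√(2 ln 2)·σ·pitch ≈ 16 µm at 8.3 µm pitch) and a mean
   window of 83 µm.  83/8.3 = 10 voxels is even; an even box filter shifts
   the output by half a voxel and would bias every centroid, so the window
   is forced to the nearest odd width (11).  Both filters use reflective
   boundaries, which keeps a constant input exactly zero after subtraction
   and avoids rim artifacts at the volume edge.
3. **Brain mask.**  Foreground is `I > 1.5 × mean(I)` over all voxels of
   the resampled raw volume, then eroded ten times.  The structuring
   element is the 6-connected cross by default (one face layer removed per
   iteration), with the 26-connected cube available by configuration.
4. **Spot threshold and labelling.**  The spot threshold is `2 × mean raw
   intensity outside the eroded mask` (the mean is the assumed statistic;
   it is logged with every run).  Candidate voxels are those inside the
   mask whose band-pass value exceeds the threshold.  Connected components
   are labelled under face adjacency (6-connectivity) by default —
   "adjacency of pixels" read literally — with 26-connectivity available.
   Each component yields one spot: an intensity-weighted centroid (weights
   are the band-pass values; a geometric centroid is available), the summed
   band-pass intensity, and the voxel/µm³ volume.

Candidate voxels are conserved: the spot volumes sum exactly to the number
of candidate voxels, and raising the spot threshold can only shrink the
candidate set.

## Regional aggregation and rankings

Spots are assigned to the atlas region under their centroid voxel — the
registration platform in the original workflow receives centroid point
clouds, so centroid granularity is the native one.  Spots over background
or in excluded regions (ventricular systems, fibre tracts, which carry
non-specific staining) are dropped and counted.  Regional tau density is
`Σ spot intensity / region volume (mm³)`; the spot-volume ratio
(`Σ spot µm³ / region µm³`) is computed alongside.  Medium-group density
pools member regions volume-weighted (`Σ intensity / Σ volume`, with an
unweighted mean available), and per-group values are averaged
arithmetically across samples.  Subregions of groups strictly above the
across-group mean form the analysis subset.  Rankings order a shared
region subset by descending log₁₀ density per sample; zero densities are
rejected (log undefined) and ties — absent by construction in synthetic
data — are broken by region id with a warning.

## Tau gradient consensus

A consensus sequence is a region list whose relative order is identical in
every sample's ranking: exactly a common subsequence of k permutations.
The maximal one is found as the longest path in the precedence DAG with
edge `u → v` iff `u` precedes `v` in all k samples.  Because every edge is
consistent with the first sample's total order, one dynamic-programming
pass over that order suffices (O(k·n²)); this is equivalent to the
incremental search that grows length-n chains from length-(n−1) chains.
Exhaustive enumeration at a fixed length runs a pruned depth-first search
over the same DAG (pruned by the longest chain reachable from each node),
with a configurable cap (default 10⁶ sequences) that aborts with a named
error in pathological cases.

Unique patterns are selected from the maximal length downward: a sequence
is retained iff it is not a subsequence of any already-retained longer
sequence (subsequence meaning order-conserved, not contiguous; an
exact-equality mode exists but never removes anything across lengths).
Partially overlapping sequences are retained.

**Permutation null.**  Each replicate draws k independent uniform
permutations of n region labels and records the maximal consensus length.
Permuting region labels of real rankings is distribution-equivalent, so
uniform permutations are drawn directly.  The tail probability
`p_at(L) = #{length ≥ L} / n_perm` is the raw proportion (the published
0.0269 = 269/10,000 is a raw proportion, not the (r+1)/(n+1) estimator),
and the significance threshold is the smallest L with `p_at(L) < α`.  With
n = 47, k = 3 and 10,000 replicates this reproduces p ≈ 0.027 at length 8
and a threshold length of 8 at α = 0.05, in about two seconds.

**Consensus network.**  Every ordered adjacent pair in a retained sequence
adds 1 to its edge's adjacency count; edge weight is count + 1 (applied
only to edges that occur — absent edges are not materialized), and all
weights are rescaled so their sum equals the normalization total (default
250) exactly.  Node attributes carry the rank of the mean regional density.
Layout uses the seeded Fruchterman–Reingold spring embedding; positions
only, rendering is out of scope.

## Detection accuracy and PET quantification

Voxel-level precision, recall and F compare a predicted mask against
expert annotation masks inside cubic ROIs (edge 423 µm, i.e. 51 voxels at
8.3 µm); per-ROI scores average over annotators.  An empty prediction
against an empty annotation is defined as F = 0 and logged — a convention
for a case the evaluation design never produces.

SUV divides frame activity (kBq/cc) by injected dose per body weight;
SUVR divides target SUV by reference (cerebellum) SUV per frame and
averages frames whose mid-times fall in the closed 45–60 min window
(frames at 47.5, 52.5 and 57.5 min under the default schedule).  Dose and
body weight cancel in SUVR by construction; this is tested by randomizing
both.

## Synthetic ground truth

The raw whole-brain volumes behind the original experiment are not
publicly deposited, so every stage is exercised on generated data whose
truth is exact.

- **Toy atlas**: an ellipsoid filling 0.46 of the field per axis (a brain
  cropped the way acquisitions are), partitioned into equal-population
  z-bands (`layered-boxes`) or radial `nested-shells`, volumes derived
  from exact voxel counts, a miniature medium-group hierarchy, and
  optional excluded regions.
- **Tau volumes**: background 10 inside the brain, 1 outside, Gaussian
  blobs (default σ = 1.2 voxels ≈ 23 µm FWHM, the scale of a tangle-bearing
  soma; amplitude 200, i.e. 20× the brain background) and Gaussian noise
  clipped at zero, sd 0.5 (5 % of the brain background, typical of
  frame-averaged light-sheet acquisitions; this also keeps the 1.5×-mean
  mask free of salt holes, which the ten-erosion refinement would
  otherwise amplify — the published workflow has no hole-filling step and
  its masks are hole-free in practice).  Blob centres are placed in the
  brain eroded exactly as the extraction mask is (ten face-connected
  erosions) shrunk further by one blob support radius (4σ) via the
  distance transform, so planted footprints survive masking; a minimum
  pairwise separation of 9 voxels (~2× the suprathreshold footprint
  radius) keeps deposits resolvable.  The ground-truth mask marks voxels
  within 2σ of a centre.
- **Detection scoring**: predicted spots are associated to planted
  deposits by the generator's own 4σ support radius; spots outside every
  support are false positives, deposits without any associated spot are
  misses, and a deposit counts as recovered when an associated centroid
  lies within one voxel of its centre.  Under 6-connectivity a deposit's
  rim occasionally detaches as a tiny extra component; such fragments
  belong to their deposit and are not spurious detections, so they do not
  count against precision.  (A voxel-level F between the suprathreshold
  footprint — radius ≈ 4σ at these settings — and the 2σ truth ball would
  measure the mismatch of two different radii rather than detection
  quality, which is why deposit-level scoring is used for the planted
  fixture; the voxel-level F-score is used for annotation ROIs, where
  prediction and truth live on the same footprint.)
- **Planted rankings**: each sample is a uniform permutation of the
  non-planted ids merged with the planted chain kept in order at uniformly
  random positions, guaranteeing the maximal consensus length is at least
  the planted length.  Densities are exponentially spaced so log₁₀
  densities are linear and strictly ordered — no ties by construction.
- **TAC pairs**: activities sampled on the 20-frame schedule (4 × 1,
  8 × 2, 8 × 5 min; mid-times 0.5 … 57.5 min), default dose 17,200 kBq in
  a 25 g animal, matching a typical injected activity.

What the generators do *not* emulate: optical anisotropy and stripe
artifacts, autofluorescent vasculature, registration error, spatially
structured (non-white) background, and biological variability in deposit
shape.  Passing tests therefore demonstrate the correctness of the
algorithms under their stated model, not robustness to real-data nuisance
structure.

## Problem sizes and numerical choices

Test fixtures use 64³ volumes with 20 planted deposits (full extraction in
well under a second) and a 96 × 64 × 64 three-sample set with a planted
15-region density gradient for the end-to-end pipeline; the permutation
null runs its full 10,000 replicates.  The band-pass is validated against
a direct-summation convolution oracle on 21³ grids to 10⁻⁶, component
labelling against a flood-fill oracle on 200 random 8³ grids for both
connectivities, and the consensus search against exhaustive subsequence
enumeration on 300 random instances with n ≤ 7.  Graph weights are
normalized by a single common factor, so their sum matches the configured
total to better than 10⁻⁹.  All randomness flows through explicit
`numpy.random.default_rng` seeds; the pipeline expands one global seed
into independent per-stage seeds via `SeedSequence.spawn`.

## Known limitations

- Spot-to-region assignment is centroid-based; components straddling a
  region boundary contribute all their intensity to the centroid's region.
- `enumerate_sequences` is exponential in the worst case (hence the cap);
  real and null ranking sets stay far from that regime.
- The pipeline accepts pre-aligned label volumes only; atlas registration
  is explicitly out of scope.
- The mask-threshold statistic ("global average") and the outside-brain
  statistic (mean) are assumptions where the workflow description is
  ambiguous; both are logged so runs are auditable.
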