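# Methods

This note records the models implemented in `gliomaseg`, their assumptions,
the defaults that matter, and the design choices made where the classical
method descriptions leave the details open.

## Scope and input model

Both segmenters operate on a single modality at a time (a FLAIR-like
contrast is the default assumption: edema hyperintense, necrotic core
between normal brain and edema). Inputs are skull-stripped and
bias-corrected volumes — background exactly zero, as brain-extraction tools
leave it. Preprocessing (brain extraction, bias correction, registration)
is out of scope; the I/O layer validates geometry but never resamples.
Volumes are reoriented to canonical RAS axis order on load so the first
voxel axis is always the anatomical left–right axis.

Non-contiguous acquisitions are first-class: `spacing[2]` is the slice
thickness, `slice_gap` the unimaged distance between slices. On disk the
thickness lives in pixdim and the center-to-center spacing in the affine;
the gap is their difference. Distances in mm use thickness + gap as the
effective z step (boundary positions are physical); volumes in mm³ use the
thickness only, because voxels in the gap were never imaged — the gap is
reported as a caveat, never silently folded in.

## Hemisphere-symmetry region growing

Assumptions: (1) the tumor occupies one hemisphere only; (2) the healthy
brain is mirror-symmetric about the midsagittal plane. Pipeline, per run:

1. **Alignment.** Exhaustive grid search over in-plane rotations
   [−20°, +20°] in 0.5° steps × midline columns in the central third of the
   x-range, maximizing the Dice overlap of the z-projected head mask with
   its reflection about the candidate column. Deterministic; ties prefer
   the smallest |rotation|. The mirroring is pure array reversal about an
   integer column (the midline column itself is excluded from both
   hemispheres), so no interpolation asymmetry enters; with the midline
   column excluded, column x pairs with column 2·mid − x.
2. **Asymmetry.** diff = |left − mirror(right)|. The noise scale is
   1.4826 × median(|signed difference|) over in-brain voxels — with the
   median of the signed difference at zero by symmetry, this estimates the
   standard deviation of the left-right intensity difference robustly, so
   the tumor's own asymmetry signal does not inflate it. Voxels with
   diff > k·scale (default k = 3) are candidates, attributed to the
   brighter side; the winning side's share of candidate mass is the
   confidence. The head rim is excluded from candidates
   (``rim_exclusion`` = 3 in-plane erosions): sub-voxel alignment residuals
   produce spurious rim differences that must not seed growth.
3. **Per-slice growth.** On each slice intersecting the candidate region
   (after in-plane area-opening of the candidate at
   ``candidate_min_area`` = 20 voxels — isolated supra-threshold noise
   voxels must not seed, since a seed on normal brain grows the whole
   brain): percentile contrast stretch (1st/99th percentile of positive
   intensities → [0, 1]), seed at the brightest candidate voxel
   (lexicographic tie-break), breadth-first growth with
   |I − I_seed| ≤ 0.2 at 8-connectivity, similarity measured against the
   seed (not a running mean — the simplest deterministic reading; a
   running-mean variant would drift). Enclosed holes are filled: the
   non-enhancing core inside the bright edema ring belongs to the whole
   tumor.
4. **Output.** Union of slice masks mapped back through the inverse
   rotation (nearest neighbor), as label 2 with ``undifferentiated=True`` —
   the method cannot separate edema from core. Confidence below
   ``bilateral_confidence_floor`` = 0.65 raises ``bilateral_suspect``:
   mirrored bilateral disease cancels in the subtraction, which is this
   method's structural blind spot (a tumor-free symmetric volume also sits
   at confidence 0.5 and simply yields an empty mask).

Defaults: tolerance 0.2, connectivity 8, stretch percentiles (1, 99),
asymmetry threshold 3×, confidence floor 0.65. All overridable via flags or
YAML config.

## Fuzzy C-means

Cost J = Σ_j Σ_i w_ij^m ‖x_j − c_i‖², memberships constrained to sum to 1
per data point; distance is absolute intensity difference (scalar feature).
Alternating updates: c_i = Σ_j w_ij^m x_j / Σ_j w_ij^m and
w_ij = 1 / Σ_k (d_ij/d_kj)^(2/(m−1)); a point coincident with a centroid
takes membership 1 there (split evenly among coincident centroids).
Convergence when the largest centroid move drops below ``tol`` = 1e-5
(intensity units) or at ``max_iter`` = 200; the cost is non-increasing
across iterations (checked to 1e-9 in the tests). Centroids are returned
sorted ascending with memberships permuted to match.

**Initialization** is deterministic: centroids evenly spaced over the
robust (1st–99th percentile) intensity range. Quantile-based initialization
was considered and rejected: on images whose histogram is dominated by one
tissue (background is typically >half the field of view) several quantiles
fall inside the same mode, and coincident centroids are a fixed point of
the iteration — the clusters can never separate. Even spacing over the
range puts one starting centroid near each intensity mode regardless of
mode mass. The RNG seed only matters for the optional random-restart mode
(off by default); two runs with different seeds produce identical masks.

**Cluster → tissue mapping** (a convention of this package; single-modality
clustering does not identify tissues by itself): C = 4 clusters
(background-ish, normal brain, necrotic, edema); after merging numerically
coincident centroids, the top intensity level is edema and the level
immediately below is necrotic where its voxels fall inside the filled
convex hull of the (area-opened) edema component — the core sits
geometrically inside the edema shell. Two guards reject tumor output on
slices that have none: the top level must be separated from the next by at
least 15% of the centroid range (otherwise the top clusters merely split
the normal-brain mode), and the edema level must hold a minority of the
non-background mass (a tumor is a minority tissue). Whole-tumor-only mode
(C ≥ 2) labels the top cluster as 2 and skips the component logic.

Cleanup: per-slice connected components smaller than ``min_area`` = 20
voxels are removed at 8-connectivity (area-opening). A consequence: tumor
cross-sections smaller than ``min_area`` on a slice are below the
pipeline's design resolution and are removed with the noise.

## Metrics

Dice 2|A∩B|/(|A|+|B|); 1.0 for two empty masks, 0.0 when exactly one is
empty (conventions logged in every report). Hausdorff is the plain
(100th-percentile) symmetric max–min Euclidean distance between boundary
voxels — foreground voxels with a face-adjacent background or out-of-volume
neighbor (the strictest common boundary definition). It is computed in 3D
via the exact Euclidean distance transform and is undefined (recorded, not
fabricated) when either mask is empty; the brute-force all-pairs
computation is kept in the test suite as the independent oracle and must
agree exactly. Voxel units are the default; mm is opt-in with the slice gap
in the z step. Components a method does not produce (region growing's
edema/necrotic) appear as "not produced" rows, and batch means exclude
undefined Hausdorff cases with an explicit excluded count.

## Phantoms

The generator emulates what the segmenters actually consume: a
brain-extracted, FLAIR-like volume. Head = ellipsoid of uniform brain
intensity (40) on exact-zero background; tumor = concentric ellipsoids,
necrotic core (60) inside an edema shell (90); background < brain <
necrotic < edema is enforced. Tumor radii are in-plane voxel radii; the
through-plane semi-axis is scaled by dx/(dz+gap) so tumors stay physically
round on anisotropic grids. Corruptions, in order: multiplicative bias
field (product of per-axis inverted parabolas, bounded by 1 ± amplitude),
additive Gaussian noise inside the head only (brain extraction leaves
exact-zero background; Gaussian rather than Rician, since at these SNRs on
magnitude images the difference is second-order for the algorithms under
test), in-plane rotation (linear interpolation for intensities, nearest
neighbor for labels). Right-lateral phantoms are constructed as exact
left-right flips of the left-lateral ones, and the head is centered on an
integer voxel column, so mirror-equivariance tests can demand bit-exact
equality. The clinical preset uses a 256×224 in-plane matrix (scaled down
from the 512×448 clinical format for speed) with 20 slices of 5 mm
thickness and 1.5 mm gap at 0.5 mm in-plane resolution.

What the phantoms deliberately do not model: cortical folding, tissue
texture, partial-volume averaging, acquisition physics, and irregular tumor
shapes. Passing tests therefore demonstrate correctness of the
implementations and their stated contracts under controlled conditions, not
clinical-grade accuracy: on real MRI both methods are known to perform far
worse (intensity overlap between tissues, anatomy that is only
approximately symmetric).

The canonical suite (`phantom_suite`) fixes six study conditions on the
clinical geometry: tumor-free noise-free (symmetry fixed point), unilateral
with large edema / small core, unilateral with large core, mirrored
bilateral (the region-growing blind spot), rotated +7°, and noisy + biased
(noise σ = 6, bias 10% — the FCM stress case). Moderate noise is σ = 4
against a 20–30 intensity-unit tissue contrast.

## Numerical choices and degenerate inputs

- Alignment ties prefer |rotation| = 0, then the smaller midline column;
  seed-selection ties are lexicographic (row, then column).
- Constant slices: contrast stretch returns zeros with a warning; FCM skips
  the slice. All-identical FCM input with C ≥ 2 returns one occupied
  centroid, the rest flagged empty, ``converged=False``.
- Hard assignment ties at level midpoints go to the higher (brighter)
  cluster.
- Non-integer label files are rejected, never rounded; NaN voxels are
  rejected with a count; 4D inputs are rejected naming the extra dimension.

## Known limitations

- The convex-hull necrotic rule assumes one compact tumor per slice: with
  two disjoint edema components (bilateral disease) the hull spans the gap
  between them and over-labels necrotic tissue there — visible on the
  bilateral fixture in the demo output.
- FCM on bias-corrupted input degrades sharply (the demo's noisy_biased
  case): intensity-only clustering cannot separate a multiplicative drift
  from tissue contrast. No spatially-regularized or bias-corrected FCM
  variant is implemented; inputs are expected to be bias-corrected
  upstream.
- Region growing is 2D slice-wise by construction and reports only the
  whole tumor; 3D growth and multimodal features are out of scope.
- The bilateral flag is a confidence heuristic: strongly *asymmetric*
  bilateral disease can keep confidence above the floor and go unflagged.
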