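# Methods

This note documents the models implemented in `cytoparcel`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic data do and do not establish about real histology.

## Grey level index (GLI)

The GLI of a measuring field is the fraction of cell-body pixels it
contains. Internally the values are exact double-precision fractions; the
traditional 8-bit image (v → round(v·255), round-half-up) is an *export
format* only, so no downstream statistic inherits quantization error. Edge
fields smaller than the full field are normalized by their actual pixel
count, which preserves the conservation identity
Σ(field value × field pixel count) = total cell pixels exactly. The field
size defaults to 16 µm and must be an integer multiple of the pixel size;
non-integer ratios are rejected rather than resampled.

## Traverses

The only hard requirements on traverses are that they run from the outer
(layer I/II) to the inner (layer VI/white matter) contour, perpendicular to
the layers, and never cross. Both properties hold for gradient streamlines
of a harmonic field: Laplace's equation is solved on the ribbon interior
with Dirichlet values 0 on the outer and 1 on the inner contour, and
streamlines are traced from seeds placed at equal arc-length intervals
(default 16 µm) on the outer contour. For parallel contours the field is
linear and traverses are perpendicular segments; for concentric arcs they
are radii; in curved cortex they bend smoothly without intersecting.

Numerics: the five-point Laplacian is solved by a sparse direct solve on a
grid capped at ~75 000 unknowns (larger ribbons are solved on a down-sampled
grid and the field interpolated bilinearly — the field is smooth, so this
loses little). Contour bands are rasterized 3 px wide; inside them the
discrete gradient vanishes, so the tracer falls back to heading toward the
nearest inner-contour point until it re-enters the live field. Tracing uses
midpoint (RK2) steps of ~0.75 px and terminates at field value 0.995, after
which the endpoint is projected onto the inner contour.

## Profiles and features

Profiles sample the GLI bilinearly at `n_depth` points equally spaced along
a traverse's arc length. `n_depth` defaults to 101 (1% steps of normalized
cortical depth). Feature extraction first resamples any profile linearly
onto the canonical 101-point grid, which makes the ten features independent
of the caller's sampling density by construction (nested grids reproduce
sample values exactly).

The ten features treat the profile g(d) as a distribution over depth
d ∈ [0, 100]:

| # | feature | definition |
|---|---------|------------|
| 1 | mean amplitude | mean(g) |
| 2 | centroid depth | Σ dᵢgᵢ / Σ gᵢ |
| 3–5 | depth SD, skewness, kurtosis | standardized central moments of d weighted by g |
| 6–10 | the same five | computed on \|dg/dd\| (central differences) |

The derivative magnitude is used because weighted moments require a
nonnegative measure; the alternative reading (moments of the amplitude
*values*) is not implemented. Degenerate profiles (zero total weight or zero
spread) take the fixed convention centroid 50, SD 0, skewness 0, kurtosis 0,
and all-zero profiles are logged. Consequences worth knowing: amplitude
features scale linearly with profile amplitude while the depth moments are
amplitude-scale invariant, mirroring a profile in depth maps the centroid
x → 100−x and negates the skewness, and a constant profile has uniform depth
moments (SD ≈ 29.15) with the derivative block degenerate.

## Border detection

At position k with block size b the profiles [k−b, k) and [k, k+b) are
compared. The pooled covariance weights each block covariance by (n−1); with
p = 10 features and 10–24 profiles per block it can be near-singular, so a
ridge of 1e-6·trace(S)/p is added to the diagonal whenever the condition
number exceeds 1e8. Sliding-window statistics are computed from cumulative
first and second moments, so a full section costs O(n) covariance builds per
block size.

Hotelling's T² = (n₁n₂/n)·D² is referred to F(p, n−p−1) via
F = (n−p−1)/(p(n−2))·T²; block sizes below 6 are rejected at p = 10 because
the second degree of freedom vanishes. The Bonferroni family is the set of
tested positions of one section at one block size; block sizes are *not*
additionally corrected against each other because they are strongly
dependent — positional reproducibility across block sizes is the filter that
plays that role.

Acceptance of a border proceeds in three stages:

1. **Local maxima.** Strict local maxima of D² per block size (plateaus take
   the leftmost index), thinned by non-maximum suppression with minimum
   separation b: windows closer than one block size share profiles and
   cannot represent distinct borders, so only the larger maximum survives.
   Without this, one strong border produces shoulder-peak duplicates.
2. **Within a section.** A maximum is a candidate if its corrected p is
   below α (default 0.001) for at least one block size, and it is kept if a
   D² maximum occurs within ±2 positions for at least half of the block
   sizes 10–24. Significance and reproducibility act as separate filters;
   demanding corrected significance in every supporting block size would
   make the weakest blocks (10–13 profiles at p = 10) the binding constraint
   and costs roughly a third of the detection power at moderate contrast.
   Kept positions within ±2 of each other merge into one call at their
   median.
3. **Across sections.** A call is accepted only if matched within
   `tol_positions` in at least 3 *consecutive* serial sections. The default
   tolerance is 6 traverses ≈ 0.1 mm at the default spacing: position
   estimates in adjacent sections carry independent noise of a few traverses
   each, while 0.1 mm is far below the extent of any cortical area.

Windows are adjacent to position k (left/right), not centered on it; the
centered variant only shifts indices by b/2 and is not separately exposed.

Measured operating characteristics on synthetic feature streams (100
profiles, border at 50, contrast = 3 pooled SDs): planted borders are
recovered within ±2 traverses in ≈ 95–97% of replicates, and homogeneous
sections produce any accepted candidate in ≤ 1% of replicates.

## Volumetry and permutation tests

V = s·T·x·y·ΣNᵢ·F is evaluated as a plain product (exact to double
precision); passing a section thickness above 1 mm triggers a unit-mismatch
warning because thicknesses are virtually always tens of µm. Normalized
volumes are fractions of the individual whole-brain volume.

The permutation test uses the difference of group means as statistic, with
the paired (sign-flip) scheme for hemisphere comparisons — hemispheres are
paired within a brain — and label permutation for sex comparisons. The
two-sided Monte-Carlo p is (1 + #{|null| ≥ |observed|})/(n_iter + 1), the
add-one estimate that can never return 0. One million iterations is the
default; the sampling error of p near 0.05 is then ≈ 0.0002.

## Clustering

Units (areas, or area × hemisphere) are represented by the mean feature
vector of their sampled profiles; the classical sampling plan is 3 sections
× ~15 profiles per hemisphere in 10 brains = 900 profiles per area. Features
are z-standardized across units before the Euclidean distance because the
ten features live on incommensurate scales (GLI fractions vs. depth
percentages). Ward linkage is delegated to scipy; merge heights are scipy's
Ward distances and are non-decreasing. Ties are resolved by scipy's
deterministic nearest-neighbor chain order, so repeated runs on identical
input agree bit-for-bit.

## Probability maps

Probability maps are plain superimpositions: voxel value = (brains labeling
the voxel)/n, so values lie on the grid {0, 1/n, …, 1}. The MPM assigns each
voxel to the argmax area; voxels where every area has probability 0 stay
background, and no minimum-probability threshold is applied by default.
Exact ties are broken by the larger mean probability over the voxel's
26-neighborhood, then by input order — a deterministic refinement of the
plain argmax rule. Centers of gravity are probability-weighted means of
voxel-center coordinates mapped through the affine; coordinate lookup is
nearest-voxel after the inverse affine, with out-of-grid coordinates
reported explicitly rather than clamped. Inputs are required to share grid
and affine; spatial normalization is out of scope.

## Synthetic data

The generator emulates exactly the structures the pipeline consumes:

- **Sections** are annulus sectors (curvature exercises the traverse
  machinery while contours and depth remain analytically exact) populated
  with fixed-radius disk "cells" by an inhomogeneous Poisson process whose
  intensity follows the area's laminar density at the local depth. The
  intensity uses the Boolean-model correction λ = −log(1−ρ)/(πr²) so the
  *observed* cell-area fraction equals the specified density despite disk
  overlap; without it, a specified density of 0.3 would realize as ≈ 0.26.
  Depth runs from 0% at the outer contour to 100% at the inner one.
- The bundled two-area fixture contrasts a granular pattern (dense layer IV)
  with a dysgranular one (faint IV, denser infragranular layers) at 2 µm
  pixels, 5 µm cell radius, 400 µm ribbon thickness and ~121 traverses —
  laminar patterns loosely in the range seen in ventral temporal isocortex.
- **Section series** share a planted border with independent uniform index
  drift per section, bounded by `border_drift_traverses` (drift is expressed
  in traverse units because every downstream tolerance is).
- **Feature populations** are multivariate normal with shared SPD
  covariance; "3-SD laminar contrast" is realized as a 3-pooled-SD mean
  shift in one coordinate (by affine invariance of D² only the Mahalanobis
  norm of the shift matters).
- **Label volumes** translate each area independently by a bounded uniform
  integer jitter; exclusivity is preserved by first-assignment-wins in label
  order, and shapes clipped at the grid edge are logged.

What passing tests on these data show: the statistics, the sliding-window
machinery, the geometry code and the aggregation logic are correct, and the
detector has the stated operating characteristics under Gaussian feature
noise and Poisson cell placement. What they do not show: performance on real
stains with artifacts (tears, vessels, tangential cuts, staining gradients),
mis-segmented cells, or non-Gaussian profile-feature distributions;
contours here are exact, whereas hand-drawn contours add their own error.

## Problem sizes and determinism

Statistical checks run at the sizes stated above (200 synthetic sections for
recovery/type-I, 2000 replicates for null uniformity, 1000 datasets × 10⁴
iterations for permutation calibration); the end-to-end pipeline fixture
uses 3 sections at ~121 traverses each. Every generator and every
Monte-Carlo routine takes an explicit seed; fixed seeds give bit-identical
outputs, and the pipeline manifest records seeds, configuration and SHA-256
hashes of all artifacts.

## Known limitations

- Traverse tracing assumes simple, consistently oriented, non-crossing
  contours; it validates ribbon topology but not contour quality.
- The harmonic-field down-sampling cap (~75k unknowns) slightly smooths the
  depth field of very large sections.
- The Bonferroni family and the adjacent-block window are one of several
  defensible conventions; both are configurable in spirit but only the
  defaults are exercised by the test suite.
- The feature moments interpret the profile as a distribution over depth;
  laboratories using amplitude-moment conventions will get different (but
  consistently different) feature values.
- MPM tie-breaking beyond argmax is a convention, not a statistical claim.
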