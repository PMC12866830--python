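# Methods

This note documents the models and numerical choices behind `taupaint`:
what each stage assumes, which parameters matter, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## Localization data model

A field of view (FOV) is a table of localizations — fitted emitter
positions from a DNA-PAINT acquisition — with coordinates in µm (readers
accept nm or µm with an explicit flag; every threshold in the pipeline is
quoted in µm/µm², so µm is the canonical unit).  Coordinates are treated as
continuous 2D points; z and the pixel grid are ignored.  Frame indices
matter only for demultiplexing two-color acquisitions recorded with
alternating laser blocks (default: 200 frames per block, two channels,
68000 frames total → 34000 frames per target).  Blinking kinetics are not
modeled anywhere downstream, so repeated detections of one docking site are
simply part of the localization count.

## Segmentation

Voronoi tessellation assigns each localization a cell whose area is an
inverse density estimate.  A localization is *retained* when its cell is
bounded and its area is at most `voronoi_area_threshold` (inclusive — ties
at the threshold are kept, mirroring the inclusive minimum-localization
rule).  Cells of points on the convex hull of the point set are unbounded,
have no defined area, and always fail; this only affects the FOV rim.
Clusters are connected components of the Voronoi edge graph restricted to
retained localizations, computed with a sparse union-find; segmented
objects with fewer than `min_locs = 10` localizations are discarded.

The cell-area threshold must be matched to the localization density of the
data — the analysis this package reimplements adjusted it per cohort
(printed ranges 0.00018–0.0003 µm² up to > 0.002 µm², shipped as
`VORONOI_THRESHOLD_PRESETS`).  The package default of `2e-3` µm² is
calibrated to the synthetic generator's default in-aggregate density
(16000 locs/µm², expected cell ≈ 6·10⁻⁵ µm²): roughly 30× the typical
in-aggregate cell so aggregate rims survive, while uniform background at
2 locs/µm² (cells ≈ 0.5 µm²) fails it by orders of magnitude.

**Aggregate boundary and area.**  Both are taken from the alpha-shape of
the member points: the union of Delaunay triangles with circumradius
≤ `alpha_radius` (default 0.05 µm).  Degenerate alpha-shapes fall back to
the convex hull.  The alternative convention — summing member Voronoi cell
areas — is available from the tessellation but is not the default, because
the two-color stage explicitly represents aggregates as alpha-shapes and a
single area definition must serve both.

## Artifact and background filters

**Artifact filter.**  Localization count scales linearly with aggregate
area, so segmented objects lie on a line in log₁₀N vs log₁₀A.  The line is
fit with the Theil–Sen estimator; the residual scale σ̂ is the scaled MAD,
floored at 0.1 dex.  Objects with |residual| > 3σ̂ are removed.  The floor
matters: with a few dozen objects the MAD underestimates the true scatter,
and an unfloored 3-MAD cut starts clipping ordinary biological variation;
0.1 dex keeps the minimum rejection threshold at a factor of 2 in count,
whereas genuine imaging artifacts (e.g. dye aggregates, fiducial residues)
deviate by orders of magnitude.  With fewer than 10 objects the fit is
meaningless and the filter is skipped with a warning.

**Background filter.**  Keep aggregates with area ≥ the dye-specific
threshold (inclusive): 0.004 µm² for Cy3b-type imagers, 0.006 µm² for
ATTO655-type, reflecting their different nonspecific-binding levels.  In
`percentile` mode the threshold is instead the 0.97 quantile (taken from
above) of negative-control object areas, so at least 97 % of
negative-control objects are removed — the calibration the fixed defaults
came from.

**Size classes.**  Nano [background threshold, 0.017), intermediate
[0.017, 0.15), micro [0.15, ∞) µm².  The printed ranges share endpoints, so
a boundary convention is required; windows are half-open with inclusive
lower edges, making classification total and single-valued.

## Morphology

`compute_descriptors` returns a fixed 67-entry vector per aggregate,
computed from the raw point cloud (no rendering): 8 point/density
statistics, 16 geometric descriptors of the alpha-shape, 12 moment
descriptors, 12 boundary descriptors, 10 skeleton descriptors, 4
fractal/heterogeneity estimates, and 5 composite indices.  The exact
67-feature list of the original shape-profiling software is published
separately; this registry is a self-contained stand-in preserving the
dimensionality and family structure.  Numerical choices:

- Boundary descriptors use the largest polygon's exterior resampled to 128
  arc-length-uniform samples; curvature comes from periodic central
  differences, and the sign-change count uses a deadband of 5 % of the
  maximum |κ| so it reflects real convex/concave alternation rather than
  sampling jitter.
- Hu moment invariants are normalized by the alpha-shape equivalent radius
  rather than µ00 (for a point set µ00 is the count and carries no length
  scale); this makes them translation-, rotation- and scale-invariant and
  keeps the first invariant informative.
- The skeleton is the morphological skeleton of the polygon rasterized on
  a 96×96 grid over its (padded) bounding square; grid resolution is
  therefore relative to object size, which makes skeleton descriptors
  exactly equivariant under dilation.  Branch statistics come from the
  8-connected pixel graph; the longest path is a weighted double-sweep
  (exact on trees, a standard approximation on graphs with cycles).
- Fractal estimators (box-counting, correlation dimension, lacunarity) use
  scales relative to the object extent, again for exact dilation
  invariance.  They are coarse estimators intended as comparative shape
  features, not precise dimensions.
- Every descriptor is translation-invariant; each carries a registered
  length exponent (value × s^e under dilation by s) asserted numerically in
  the test suite.

Aggregates with fewer than 10 localizations or with degenerate (collinear)
geometry raise a descriptor error naming the failing family.

**PCA and group overlap.**  Features are centered and scaled to unit
variance (zero-variance features dropped with a log entry), then
diagonalized; component signs are fixed by making each axis's
largest-magnitude loading positive, so the embedding is deterministic.
Group overlap is the Jaccard index — intersection area over union area — of
two footprint polygons in the PC1–PC2 plane.  Footprints are alpha-shapes
of the projected scores with a data-adaptive radius (5× the median
nearest-neighbor distance; convex hull as fallback and as an explicit
option) after trimming the most extreme 1 % of points per group, which
stabilizes the outline against single stragglers.  The literal
intersection-over-sum-of-areas variant is available behind `mode="sum"`.
Overlap values depend on the footprint construction; on synthetic data the
identities (identical ⇒ 1, disjoint ⇒ 0, monotone decrease with group
separation) are what the suite asserts.

## Two-color analysis

Channels are pooled into a single reference point cloud and segmented once
with the single-color parameters, so both marks share one aggregate set;
per-channel member counts are kept.  Registration between channels is
assumed perfect (chromatic-offset correction is out of scope).

**Overlap quality control.**  Per aggregate, each channel's localizations
become an alpha-shape; the directional overlap of channel A is the
percentage of A's area covered by the A∩B intersection (and symmetrically
for B).  The reported score is the minimum of the two directional values; a
channel with fewer than 3 localizations makes the score 0 and flagged.
Aggregates above 0.15 µm² pass untouched (micro-aggregates are reliably
genuine, and the area gate is applied first).  A smaller aggregate is
re-segmented only when *both* directional overlaps are below 30 % — the
signature of two channel-pure structures merged in the reference.  Gating
on the minimum alone would also split singly-modified aggregates, where the
minor channel's small footprint sits inside the major one's; which
directional statistic the original gate used is not documented, and the
both-directions rule is the one that only fires on genuine merges.
Re-segmentation reruns the Voronoi pipeline per channel on the aggregate's
own members; fragments below `min_locs` are re-attached to the nearest
substantive piece, so the output clusters partition exactly the input
localizations, and pieces are re-classified by area.

**Enrichment.**  score = (n_A − n_B)/(n_A + n_B); undefined when both
counts are zero.  |score| > 0.8 ⇒ singly modified (sign picks the
channel); scores in [−0.8, 0.8] — boundaries included, per the reading
"between −0.8 and 0.8" — are dually modified.  The cutoff is configurable.

## Statistics

Group inference uses the unpaired Wilcoxon rank-sum (Mann–Whitney) test on
per-replicate means — never per-FOV values, which are pseudo-replicates of
a tissue section.  Exact small-sample p-values (full enumeration) when both
groups have ≤ 8 tie-free values, normal approximation with tie correction
otherwise; a one-sided variant serves directional hypotheses such as a
dephosphorylation-induced decrease.  No multiple-testing correction is
applied, matching the unadjusted reporting convention of the source
analysis.  Control analyses: Pearson/Spearman correlation of per-channel
counts across aggregates (steric hindrance between the two antibody stacks
would show as a negative correlation), and a per-class rank-sum comparison
of localization counts between single- and dual-color runs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the photophysics:

- **Aggregates.**  Three classes with truncated-normal characteristic
  sizes: nano discs (diameter 0.095 ± 0.008 µm, truncated to
  [0.08, 0.12]), intermediate ellipses (major axis 0.50 ± 0.05 µm in
  [0.38, 0.58], axis ratio 2.2), micro fibrils/ellipses/amorphous blobs
  (major axis 1.6 ± 0.2 µm in [1.2, 2.0]).  Class averages follow the
  observed ≈ 90 nm / ≈ 500 nm / ≈ 1.6 µm aggregate classes; the spreads
  are generator choices set so that realized alpha-shape areas fall inside
  the corresponding area windows with high probability (verified by the
  suite's Monte-Carlo checks).  Fibrils are smoothed random polylines with
  Gaussian transverse spread (σ = 0.05 µm); blobs are unions of 3–5
  overlapping discs.
- **Counts.**  n_locs = density × expected alpha-shape area ×
  10^N(0, 0.08): localization count scales linearly with aggregate area
  (the physical basis of the enrichment score) at a default in-aggregate
  density of 16000 locs/µm², with log-normal scatter standing in for
  labeling-efficiency variation.  The per-shape area factors calibrate the
  geometric area to the area the pipeline itself measures (alpha-shape of
  the jittered point cloud), so density is uniform across shapes as seen
  by the artifact filter.  At this density a nano-aggregate yields
  ~100–150 localizations — enough that its concave hull fills the planted
  disc; at much lower counts hull shrinkage biases areas down by ~20 %.
- **Jitter.**  Isotropic Gaussian localization jitter, σ = 0.01 µm, a
  typical DNA-PAINT localization precision.
- **Channels.**  Each aggregate has a channel fraction f; exactly
  round(f·n) localizations (a random subset) carry channel A, so the
  planted enrichment 2f − 1 is an exact property of the aggregate.  A
  Bernoulli(f) assignment would add binomial noise of ±2√(f(1−f)/n) to the
  *ground truth itself* (≈ 0.14 at n = 50), conflating label-sampling
  noise with pipeline error; the exact allocation keeps recovery error a
  measurement of the analysis.  `dual_mix` draws fractions from a
  three-component mixture (channel-pure ends and a central dually band)
  with configurable weights.
- **Noise.**  Uniform background (2 locs/µm²) plus small noise clusters
  (0.02/µm², 4–9 localizations, σ = 0.015 µm) emulating negative-control
  images; by construction every noise cluster fails the min-10 filter, so
  the pipeline's ≥ 97 % noise-removal behavior is testable against ground
  truth.
- **Hierarchy.**  Cohorts are group × replicate (tissue section) × FOV
  with per-FOV seeds spawned deterministically from one master seed.

Not emulated: binding kinetics and blinking statistics, photon noise and
localization-precision heterogeneity, camera artifacts, drift, chromatic
offset, 3D structure, and spatial correlation between aggregates beyond a
minimum-separation placement rule.  Consequently, passing recovery tests
demonstrates the correctness and calibration of the analysis chain on data
satisfying its assumptions — not robustness to the full physics of tissue
imaging.

## Problem sizes

The validation suite runs the full pipeline on 8 single-color FOVs
(50×50 µm, ~60k localizations each) and 3 dual-color FOVs for recovery
statistics, 50 randomized instances (≤ 500 points) against a brute-force
clustering oracle, and exact rank-sum enumeration up to group size 8.
These sizes give stable statistics (hundreds of aggregates and noise
objects per cohort) while keeping the suite fast.

## Known limitations

- Alpha-shape area depends on `alpha_radius`; areas near class boundaries
  can change class under a different alpha.  The default 0.05 µm suits
  point spacings well below 50 nm.
- The skeleton raster (96² px) limits branch resolution for very thin
  fibrils; skeleton counts are comparative features, not exact graph
  invariants of the underlying structure.
- Voronoi thresholding erodes the outermost localization shell of an
  aggregate when the threshold is close to the in-aggregate cell area;
  thresholds should be ≥ ~10× the expected in-aggregate cell area.
- PCA group-overlap values are footprint-construction-dependent and should
  be compared only within a fixed construction.
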