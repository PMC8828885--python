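# Methods

This note records the conventions, defaults and design decisions behind
`tissuemux`, and what the synthetic validation studies do and do not show.

## Coordinate and intensity conventions

Images are 0-based arrays with origin at the top-left; a pixel is addressed
as (row = y, col = x) and all distances are measured between pixel centres,
so squared pixel distances are integers. Physical coordinates are pixel
coordinates times `pixel_size_um`. Intensities are non-negative floats; a
normalised stack has every value in [0, 1]. "Positive" after thresholding
always means *strictly greater than* the threshold, so an all-zero
background stays negative at threshold 0.

## Normalisation

Each channel is rescaled by its `percentile` (default 99) computed with
linear interpolation between order statistics; values above the percentile
clip to 1. Clipping keeps downstream thresholds inside [0, 1]; the handful
of saturated pixels it affects are exactly the hot tail the percentile is
there to suppress. The percentile can be taken per image (default, robust to
per-sample staining variation) or pooled across all samples of a run (one
threshold per marker for the whole experiment); both appear in the run
configuration because either can be appropriate depending on staining
uniformity.

## Thresholding

Otsu and multi-class Otsu thresholds are computed on a 256-bin histogram of
the channel's observed range (scikit-image implementation). 256 bins is this
package's fixed contract — histogram-based thresholders differ across tools
precisely because the bin count is rarely stated. The multi-class variant
with `c` classes and `b` background classes keeps the top `c − b` classes.
Constant channels (or channels with fewer distinct values than classes) are
rejected as degenerate rather than silently thresholded.

## Mask recipes

A mask recipe is an ordered program over one or more sources (channels or
previously built masks): thresholding steps, Gaussian smoothing (permitted
before the threshold, to suppress small hot artefacts), disk dilation and
opening, hole filling, and set operations. Conventions:

* Disk structuring elements contain pixels with centre distance ≤ radius.
  They are applied through Euclidean distance transforms — exactly
  equivalent to stamping the rasterised disk, and fast even at radius 150.
  Erosion (inside opening) treats out-of-image pixels as background.
* `fill_holes(a)` fills 4-connected background components of area strictly
  below `a` that do not touch the image border; border-touching background
  is open tissue boundary, not a hole.
* `union` merges the working images; a recipe ending with several working
  images is unioned implicitly. `subtract`/`intersect` reference previously
  built masks by name.

## Segmentation

Nuclei are 4-connected components of the thresholded nuclear channel,
filtered by equivalent diameter `2√(area/π)` (the paper-free definition of
"diameter" used throughout), then relabelled 1..N in raster order of each
component's topmost-leftmost pixel so labels are deterministic. Touching
nuclei are **not** split; declumping is out of scope and a documented
limitation — planted fixtures therefore keep nuclei separated.

Expansion modes:

* `isotropic(d)` — nearest-nucleus growth by Euclidean distance ≤ d.
* `radial(d)` — the same growth restricted to membrane-mask-positive pixels
  (the most restrictive reading of growing "over" a membrane mask).
* `watershed` — watershed of the distance-to-nearest-nucleus surface seeded
  by the nuclei, restricted to nucleus ∪ membrane pixels.

In all modes nucleus pixels keep their labels, cells are disjoint, and a
contested pixel goes to the nearest nucleus with exact ties (integer squared
distances) broken toward the lower label, making the output independent of
traversal order. Pixels that end up not 4-connected to their own nucleus are
trimmed. Per-cell features are the arithmetic mean of each channel over the
cell's pixels and the unweighted centroid of pixel centres. A label image
from any external segmenter can replace detection/expansion and flows
through feature extraction unchanged.

## Phenotyping

Overlap rules use the cell's full pixel set (not bounding boxes) and the
cell's own area as denominator; "at least" boundaries are inclusive (a 30 %
rule admits exactly 30 %). Highest-overlap typing first filters rules by
their own minimum fraction, then takes the argmax, ties to the rule listed
first (counted and logged). Gates evaluate boolean threshold expressions on
the mean intensities, optionally scoped within a parent gate's cells.

Clustering: optional per-marker z-scoring (constant markers dropped with a
warning), PCA (`n_pcs` components, deterministic full SVD), a
union-symmetrised k-nearest-neighbour graph (unit weights, default k = 20),
and Louvain community detection at the configured resolution. Louvain was
chosen over Leiden deliberately; the igraph implementation is driven by a
seeded random generator. Cells are internally reordered by a lexicographic
sort of their PCA coordinates (rounded to 1e-8) before graph construction,
which makes the partition invariant to input row order; cluster ids are
assigned 1..K by descending size. The profile table reports mean raw (not
z-scored) intensity per marker per cluster. The z-score → PCA contract is
this package's own preprocessing definition for intensity data; other
toolchains log-transform or select variable features first, so cluster
boundaries need not transfer across tools. A 2-D UMAP embedding is offered
for reporting only and is deterministic given the seed.

## Spatial statistics

* **Homotypic**: DBSCAN on centroids in µm. The reachability radius can be
  given directly or derived from a density: a disk of radius ε holding
  `minPts` cells at density ρ cells/mm² gives ε = √(minPts/(π·ρ)) — this is
  the package's concrete reading of a "density" reachability parameter.
  Cluster 0 is noise; clusters are numbered by descending size.
* **Heterotypic**: per source cell, the Euclidean distance to the nearest
  target centroid within the same sample; a cell present in both sets never
  matches itself. Proximity classification is strict (`< cutoff`).
* **Group comparison**: distances pooled per group across samples (matching
  cell-level test sizes; a per-sample-median summary would test a different
  hypothesis and is not the default), two-sided Wilcoxon rank-sum with
  tie-corrected normal approximation and continuity correction, BH across
  the comparison list. A comparison is *relevant* only when |Δ median| meets
  the relevance threshold (default 8 µm ≈ one B/T-lymphocyte diameter) and
  the BH q-value is below the cutoff (default 0.1) — statistical
  significance alone is deliberately not enough.
* **Permutation null**: the statistic is the difference between group
  medians of pooled nearest distances. Each of K permutations (default
  10 000) independently reshuffles the cell-type labels among *all* cells in
  each sample — positions fixed, type counts preserved — and the two-tailed
  p-value is `(1 + #{|δ*| ≥ |δ|})/(K + 1)`; the +1 correction avoids p = 0.
  BH is applied across the tested comparisons. Because positions are fixed,
  per-sample distance matrices are precomputed once and each permutation is
  a submatrix minimum, which is what makes 10⁴ reshufflings cheap.

## Pixel-positive areas

The numerator expression is evaluated pixelwise over marker masks and then
intersected with the denominator region before counting, so the fraction is
the share of the *denominator* that is positive; numerator pixels outside
the denominator never count. Fractions are unit-free; areas convert to µm²
via `pixel_size_um²`. An empty denominator is an error, not a zero.

## Synthetic data

The generator emulates exactly the data features the pipeline consumes:
rectangular/half-plane compartments with per-channel background, disk cells
with concentric nuclei placed by rejection sampling (up to 10⁴ attempts,
non-overlap enforced with a minimum gap), per-type marker expression drawn
from zero-truncated Gaussians painted uniformly over each cell, and additive
Gaussian noise clipped at zero. Disk cells keep every oracle analytic
(centroids, areas, overlap fractions). Not emulated: irregular morphology,
marker spillover, illumination fields, cell crowding/declumping — so a
passing pipeline here demonstrates correctness of the algorithms, not
robustness to those real-data artefacts.

Grouped samples for the distance machinery are point patterns: every cell of
every type is placed uniformly with labels independent of positions, so at
shift 0 identities are exchangeable within samples and the permutation null
is exact. A planted effect moves each source cell in group A straight toward
its nearest target by `shift_um` (stopping 0.5 µm short), lowering group A's
pooled median by about the shift while group B and all target/other
positions are untouched.

## Validation study sizes

The validation studies (`tissuemux.validation`, driven by
`scripts/acceptance.py`) use sizes chosen as a small but representative
experiment: 54 planted cells of three types in a 400×400 px field with 50
noise-sd expression separation for recovery; 180 cells in three expression
blobs for clustering; 1 mm² fields with 40 source / 15 target / 30 other
cells per sample, 4 samples per group and 200 reshufflings over 500
replicate datasets for calibration (the nominal rejection probability on the
discrete p-grid is 10/201 ≈ 0.0497); 8 samples per group and 50 replicates
for the 30 µm planted-shift detection; 8 samples spanning 10–60 % planted
positive cells for the pixel/cell correlation; and a two-sample, two-stage
workflow for byte-level reproducibility.

## Known limitations

* No declumping of touching nuclei; dense tissue will under-segment.
* No illumination correction, spillover compensation or pixel classifiers.
* `.mcd` binaries are not parsed; convert to ablation text or TIFF upstream.
* Louvain on kNN graphs is sensitive to k and resolution in ways z-scored
  intensity data inherit from any graph clustering; the cross-validation
  against threshold gating is the intended guard.
* The permutation null assumes within-sample exchangeability of identities;
  organised tissue violates this, so its p-values are a baseline against
  spatial randomness, not a test of biological mechanism.
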