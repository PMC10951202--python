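# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Atlas model

An atlas plate is a 2D integer label raster (pixel value = region id, 0 =
"outside atlas") paired with a region ontology in Allen structure-graph form
(id, acronym, name, parent id). Ontology validation rejects duplicate or
zero ids, dangling parents and cycles; parent links form a forest. Rasters
are indexed (row, column), 0-based; a point (x, y) means x = column,
y = row, with pixel centers at integer coordinates — one convention
throughout, so region lookup cannot be off by one. Cells that land on label
0 are retained and flagged *unassigned* rather than dropped: an unregistered
object is information, not noise. Counts roll up the hierarchy by
re-attributing each region to its ancestor at the requested depth and
summing, which conserves totals by construction.

## Synthetic data generator

The generator exists so that every downstream stage can be validated against
known ground truth; its defaults are the package's reference study
conditions.

**Toy atlas.** Region territories are cells of a capacity-balanced power
diagram: seed points are sampled uniformly, Lloyd centroid updates keep
cells compact, and per-seed weights are adapted (80 iterations, on a grid
coarsened to ~256 px on the short side for speed) until areas are
near-equal. Power cells are convex, so regions are contiguous; near-equal
areas (±3%) make a fixed per-region cell budget geometrically feasible
everywhere, which plain Voronoi tessellation (areas varying ~3-fold) does
not.

**IF sections.** Nuclei are isotropic Gaussian-profile discs (amplitude 160,
σ = 0.6·radius, truncated at 3σ) on a background of level 20 with Gaussian
noise SD 5, radius drawn uniformly from 2–3 px — compact bright blobs with
DAPI-like morphology. Placement is uniform within each region with a global
minimum separation of 2× the maximum radius (6 px by default), enforced by
rejection sampling with a 1000-retry cap per cell; exceeding the cap raises
an error naming the region rather than silently overlapping nuclei. Each
cell draws its class from the region's mixture and its signal intensity
from N(m_class, s_class) with defaults m = (40, 100, 180), s_class = 10 on
an 8-bit-like scale; the signal channel deposits that intensity over a disc
of 1.6× the nucleus radius (maximum where discs overlap), so the mean over
a detected nuclear mask recovers the cell's intensity up to background.
The inter-class gaps of 60 and 80 units against within-class SD 10 give a
separable but not trivial classification problem with realistic boundary
misclassification.

**Class mixtures.** Per-region mixtures default to Dirichlet(2, 6, 2)
(mean weights 0.2 / 0.6 / 0.2 with substantial regional spread). This is
the configuration the mean±SD rule is built for: low and high are by
definition the tails of the dataset-wide intensity distribution, so a
realistic section has a medium majority. It also places the pooled μ±σ
thresholds inside the inter-class gaps; with near-uniform mixtures the
pooled SD is dominated by between-class spread and the rule's threshold
lands within ~1.5 within-class SDs of the high-class mean, biasing
recovered prevalence noticeably — a property of the rule itself, not of any
implementation.

**DAB pairs.** The chromogenic image is a bright field (level 235, noise
SD 3) with dark particles (level 60) grown as random 4-connected blobs of
exact pixel area drawn from the requested range, placed with a 1-px clear
moat so no two particles touch under 8-connectivity; the counterstain
raster holds dark nuclei discs. Ground truth records both counts and every
particle area.

**Misalignment.** A sampled affine (rotation, isotropic scale about the
image center, translation) composed with a smooth anchor displacement field
(Gaussian-kernel interpolation of per-anchor jitters, length scale ¼ of the
image side). The forward point mapping is exact and exported — it supplies
landmark/anchor pairs standing in for the human-placed correspondences of
an interactive alignment. Image resampling is bilinear; the inverse map
under the nonlinear part is computed by fixed-point iteration (4 steps),
which is exact for pure affines and accurate to well under 0.1 px for the
jitter magnitudes used. Out-of-bounds pixels take the stated background
level.

**What is not emulated:** point-spread functions, channel bleed-through,
tiling/stitching artifacts, uneven illumination, anisotropic or overlapping
nuclei, autofluorescence texture. Passing tests therefore demonstrate the
correctness of the measurement and geometry chain, not robustness to every
real-microscopy nuisance.

## Nucleus detection and measurement

The detection chain approximates interactive-tool nuclear segmentation with
the parameters practitioners tune (sigma, background radius, threshold):
Gaussian smooth (σ = 1.5 px) → local background removal by grey opening
with a disc (radius 8 px; skipped when 0, and exactly invariant to adding a
constant to the image) → binarize (threshold 30) → fill holes → split
touching objects by watershed → area filter (10–400 px). Defaults were
chosen on synthetic fixtures; the source tools do not publish theirs.

One deliberate choice: watershed markers are the intensity maxima of the
processed image, and flooding runs on the inverted intensity surface rather
than the distance transform. Touching nuclei of similar size produce a
near-flat distance-transform ridge with a single maximum, which merges
them; the intensity profile keeps one peak and one basin per nucleus. On
the reference section (20 regions × 200 cells, 6 px separation) this gives
precision 1.00 and recall 0.99 at 3-px centroid matching. Centroids are
intensity-weighted, which keeps them on the blob center even when a split
mask is asymmetric.

Whole-cell measurement dilates each nuclear mask by the ring width with
contested pixels assigned to the nearest nucleus (generalized Voronoi via
`expand_labels`); ring width 0 makes whole-cell identical to nuclear.
Background correction averages the mean intensity of ≥1 signal-negative
ROIs and subtracts it, clamping at 0; the correction value is recorded in
the cell-table metadata. The `auto_background_rois` helper scans a
deterministic grid for cell-free windows, shrinking the window on dense
sections. On crowded sections the estimate can absorb some perinuclear
signal, shifting all corrected values by a constant — class assignments are
invariant to such shifts because the classifier thresholds shift
covariantly.

## Intensity classification

μ is the arithmetic mean and σ the sample SD (n−1 denominator — the
convention is recorded in the persisted classifier JSON since the choice is
not forced) of the training pool's per-cell intensities. Classes: low if
I < μ−σ, high if I > μ+σ, medium otherwise. Boundary values are medium:
the verbal definitions ("one SD or less below", "one SD or more above")
overlap at the boundaries, and strict inequalities for the tail classes
make the rule total and deterministic. A zero-variance pool yields σ = 0
with a warning and classifies everything medium. The training pool is
configurable (per-section, per-animal, global); per-section is the default.
The rule is invariant to positive affine rescaling of the intensities
(μ and σ transform covariantly), monotone in intensity, and partitions
every cell into exactly one class — all property-tested.

## Pixel classification and particle counting

The chromogenic positive-cell classifier is a transparent L2-regularized
logistic regression over multi-scale features (Gaussian smooth + gradient
magnitude at each scale, default scales 1, 2, 4 px), trained on sparse
positive/negative pixel annotations from ≥1 image, with features
standardized and the solver run to tight tolerance so training is
reproducible and label-swap gives exactly complemented probabilities. Any
probabilistic classifier could sit behind the same interface. Counting
binarizes the probability map at the cutoff (0.5), takes 8-connected
components, and keeps areas **strictly greater than** the minimum size
(default 5 px: a 6-px particle counts, a 5-px one does not — the literal
reading of "greater than 5 pixels"). Relative density is
100 · n_positive / n_hematoxylin and may exceed 100; a zero counterstain
count is an explicit error, not a zero.

## Registration

Registration is geometry only: landmarks and anchors are inputs, standing
in for the human-guided plate alignment; no intensity-based optimization.
The affine is the least-squares solution over ≥3 non-collinear landmark
pairs (collinearity raises an error — no pseudo-solution). Anchor
refinement adds a displacement field interpolating the anchor residuals
(target − affine(source)) exactly, evaluated at section coordinates:
thin-plate-spline with zero smoothing for ≥3 non-collinear anchors. With
1–2 anchors a TPS is underdetermined — the r²·log r kernel vanishes at its
own node, so a single-node nonzero displacement needs the polynomial term,
which would displace the whole plane rigidly; a Gaussian-kernel
interpolant (length scale 64 px) is used instead, still exact at the nodes
with displacement decaying away from them. Anchors are reproduced to
≤1e-6 px in either regime, and refinement can only reduce anchor
residuals. Label lookup is nearest-pixel (labels are categorical; no
interpolation). Downsampling for registration-at-reduced-scale is
block-mean (preserving intensity statistics), with trailing partial blocks
averaged over available pixels; an affine fitted at reduced scale is lifted
to full resolution by scaling its translation column.

## Regional statistics and concordance

Prevalence tables report class counts and percentages per region at a
configurable ontology depth (default: leaf), with region 0 as a separate
"unassigned" row and empty regions reporting absent (NaN) statistics —
"no data" and "0%" are different claims, and absent regions are excluded
pairwise from correlations with the exclusion count reported.
Colocalization fractions (percent of marker-positive cells that are
signal-positive) default to signal-positive = class ∈ {medium, high} on
corrected intensity, configurable because the source analysis does not give
its positive call as a formula. Intensity-per-volume divides summed
fluorescence by region voxel count.

Concordance pairs one class's prevalence across matched regions (≥3
required, each with ≥ min_cells cells): Pearson r with the two-sided p from
the t transform at n−2 df, OLS slope/intercept, and 95% prediction
intervals from the standard OLS formula. Their calibration is checked by
Monte Carlo (fresh observation at every x, 2000 replicates: empirical
coverage 0.95 ± 0.01). Correlation p-values are reported unadjusted, since
the reference analyses report per-panel p; a Bonferroni flag exists for the
three-class family. Group comparisons use a two-factor ANOVA with Type II
sums of squares (the unbalanced-data choice is recorded in the output) and
the interaction included when every occupied cell has ≥2 observations;
Tukey–Kramer adjusted p-values across the factor-cell means come from the
studentized range distribution evaluated exactly (not interpolated
tables), and the whole decomposition is verified against a brute-force
textbook implementation to 1e-8 on balanced designs.

## Heatmaps

Each region's pixels take the colormap value of its statistic (default
viridis over the observed range); regions with absent statistics render
neutral grey, distinct from the colormap minimum; outside-atlas pixels stay
white. The value→color mapping and range are emitted as a JSON sidecar —
the mapping function is the contract, not the exact bytes of any PNG.

## Problem sizes

The reference validation scenarios are: detection — 512×512 plate, 20
regions × 200 cells; end-to-end prevalence recovery — 1024×1024 plate, 20
regions × 500 cells, 10 seeds (the larger plate keeps 500 cells/region
feasible at 6-px separation, which 512×512 cannot hold below the
random-sequential-packing limit); registration — 50 random affines with 8
noisy landmarks; interval coverage — 2000 replicates × 20 positions;
chromogenic counting — 3 training images, one held-out 512×512 evaluation
image.

## Known limitations

* Detection assumes roughly isotropic, non-overlapping nuclei of similar
  scale; heavily overlapping or elongated nuclei will merge or split.
* The classifier is a global two-threshold rule; bimodal within-class
  intensity structure or strong section-to-section staining drift should be
  handled by choosing the training-pool scope, not by the rule itself.
* Registration quality is bounded by landmark/anchor quality; there is no
  automatic alignment and no 3D plate interpolation between coronal levels.
* The pixel classifier is linear in its multi-scale features; stains whose
  positive class is not separable in that space need a richer model behind
  the same interface.
* Prevalence estimates carry binomial sampling noise (~2 pp SE at 500
  cells/region for a 20% class); small regions should be aggregated up the
  ontology before comparison.
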