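# Methods

`brightcell` detects cells in deliberately defocused bright-field microscopy
frames and turns per-frame counts into population-growth statistics. This
note records the model behind each stage, the parameters that matter, the
numerical choices made where the design was open, and what the synthetic
validation does and does not establish.

## The imaging model

Acquisition a few tens of microns below the focal plane trades texture for
contrast: each cell body renders as an evenly dark blob, surrounded by a
bright halo, on a bright background whose illumination varies smoothly
across the field of view and drifts over a multi-day movie. The pipeline
treats a frame `I(x)` as

    I(x) = B(x) · F(x) + ε(x)

with `B` the smooth illumination surface, `F` a reflectance-like ratio field
(≈ 1 on background, ≈ 0.4–0.7 inside cells, > 1 in halos), and `ε` sensor
noise. All detection happens in the ratio image `I/B` after halo clipping.

## Stage 1 — background estimation

The frame is cut into overlapping square tiles (default 30 px tiles, 15 px
overlap, so a 15 px lattice step). Each tile is summarized by the first four
standardized moments of its intensity histogram (mean, variance, skewness,
excess kurtosis); the moment vectors are z-scored across tiles and clustered
with DBSCAN (defaults eps = 0.1, MinPts = 6). Tiles containing cells have
inflated variance and skewed histograms, so background-only tiles form the
dominant dense cluster; that cluster is taken as background and everything
else — including DBSCAN noise points — is conservatively treated as mixture.

Two choices here are deliberate:

* **Adaptive radius.** eps is a *starting* radius. If the densest cluster
  holds under a quarter of all tiles it cannot be the background, which
  must dominate any frame this method is suited to; the radius is then
  doubled and clustering repeated (at most 7 attempts). Crowded frames are
  untouched — their first attempt already dominates — but nearly
  featureless frames, where z-scoring stretches pure sensor noise to unit
  scale, would otherwise fail outright.
* **Surface fit.** Each background tile contributes one seed point (tile
  center, tile mean intensity). A thin-plate-spline RBF interpolant with
  k-nearest-neighbor locality (k ≤ 64, slight smoothing) is evaluated on a
  4-px lattice and bilinearly upsampled; the illumination field is smooth by
  assumption, so the decimation is exact in practice and keeps the fit
  linear-time in image area. The surface is floored at 1 intensity unit so
  the subsequent division is always defined.

The corrected image is `I/B` with every value above 1.0 (the halos) clipped
to 1.0, leaving values in (0, 1] with background pinned at 1.

## Stage 2 — MSER foreground detection

Cell bodies are found as maximally stable extremal regions of the corrected
image, rescaled to 8 bits. The rescaling maps `[lo, 1.0] → [0, 255]` with
`lo = min(image minimum, 0.7)`: cell interiors darken the ratio image by at
least ~30%, so the anchor never stretches a foreground-free frame's noise
into fake contrast (without the clamp, a blank frame yields phantom
regions).

For thresholds τ = 0…255 the 4-connected components of `{I ≤ τ}` form a
nested component tree. A component R at level τ is scored by

    variation(R, τ) = (|R⁺| − |R⁻|) / |R|,

where R⁺ is the component containing R at level min(τ+Δ, 255) and R⁻ the
largest component contained in R at level max(τ−Δ, 0) (area 0 if none).
A region is reported when its variation is a local minimum along its branch
— no child at τ−1 scores strictly lower, and its parent at τ+1 scores no
lower, ties resolved toward the coarser region — and it passes the filters
minSize ≤ |R| ≤ maxSize and variation ≤ maxVariation (defaults Δ = 5,
30 px, 4000 px, 1.0). The component spanning the whole frame is excluded on
principle: it has no boundary and is not extremal. Reported regions are
unioned into a binary mask and interior holes (8-connected background
components with no path to a border) are filled; the complementary 4/8
connectivity pair avoids topological paradoxes.

The detector is implemented as an explicit level sweep with incremental
parent maps (linear in pixels per level) and is validated, pixel for pixel,
against `brightcell.mser_reference` — an independent brute-force
implementation that materializes every threshold component as a pixel set
and applies the same formulas by direct enumeration.

## Stage 3 — clump splitting and merge repair

Touching cells segment as one blob. Seeds are the regional maxima of the
Euclidean distance transform of the mask (ultimate erosion); a marker-
controlled watershed on the negated distance transform, restricted to the
mask, then assigns every foreground pixel to a seed basin, so the union of
the split labels equals the mask exactly.

Numerical choice: the EDT is quantized to **half-pixel steps** before
maxima extraction. On the integer grid the EDT of a convex body is a
near-equal plateau whose strict maxima are scattered single pixels; the
quantization collapses them to one seed component per body, while genuine
saddles between touching cells dip by well over half a pixel and survive.
(Integer flooring, the obvious alternative, merges saddles whose dip
straddles an integer boundary; on the cluster benchmark below it resolves
88% of clusters versus 93% for half-pixel steps.)

Spurious extra seeds over-split some cells. The repair pass models
foreground and background intensities in the corrected image as Gaussians
(sample mean/variance over the mask and its complement, variances floored
at 1e-8). Merge candidates are labels with area in [30, 1000] px and
eccentricity above 0.7 — small elongated fragments. For each candidate,
smallest first, neighbors are ranked by shared interface length (the 1-px
dilation overlap in both directions); a merge is accepted when the mean
per-pixel Gaussian log-likelihood of the interface band is higher under the
foreground model than the background model *and* the merged object's
eccentricity stays below 0.7. The pass iterates to a fixed point, so
running it twice changes nothing. Interfaces between genuinely distinct
touching cells are slightly brighter than cell interiors (a property of
defocused acquisition), and the union of two full cells is elongated, so
both tests guard against re-merging correct splits.

## Stage 4 — measurement and filtering

Per object: area in pixels, eccentricity of the ellipse with identical
normalized second central moments (0 = circle, → 1 = line), centroid, and
border contact. Objects are discarded when area < 50 px **or** eccentricity
> 0.99 (debris and line-like artifacts; thresholds boundary-inclusive as
stated, so area 50 and eccentricity 0.99 survive), and border-touching
objects are removed because their features are truncated. Survivors are
relabeled contiguously.

## Evaluation scheme

Against a ground-truth label grid, each true cell is assigned the detected
object containing its centroid (maximal-overlap fallback). Cells sharing a
detected object are under-segmented; a cell covered by additional detected
fragments (each mostly inside it) is over-segmented; a cell whose object
covers less than half its area, or no object, is missed; detected objects
claimed by nothing are debris. Detection tallies follow the standard
counting convention: TP = correct cells + over-segmented cells (largest
fragment) + one per under-segmented object; FP = debris + surplus
fragments; FN = missed + remaining cells of under-segmented objects. The
derived rates are accuracy = TP/(TP+FP+FN), specificity = TP/(TP+FP),
sensitivity = TP/(TP+FN); accuracy never exceeds the other two. The 0.5
overlap threshold and centroid-containment rule are this package's
automation of a protocol that was originally manual; both are configurable.

## Growth analysis

With sampling every few minutes, the pointwise doubling time needs no
parametric fit: counts are smoothed by a centered moving average (default
window 1 h — raw counts are Poisson-noisy at low N), and for each time t
the first later time t₂ with N(t₂) ≥ 2·N(t) is found by linear
interpolation between bracketing samples; DT(t) = t₂ − t, undefined (NaN)
once the series never doubles again. The estimator is invariant to time
shifts and count rescaling.

The three canonical culture phases (sub-exponential lag, exponential
growth, plateau) are formalized as a two-breakpoint piecewise-linear fit to
log₂ counts: a grid search over candidate breakpoint pairs (60 candidates
per axis, O(1) segment fits via prefix sums, ≥ 4 points per phase)
minimizes total squared error; each phase's slope converts to a doubling
time ln 2 / slope (infinite for flat phases). This formalizes what a
log-scale plot shows by eye and is labeled as such in reports.

## Synthetic data: what it emulates and what it does not

The generator renders the *phenomenology* of defocused bright-field
acquisition, not its optics: a planar or quadratic multiplicative
illumination surface (default 110–170 intensity units); elliptical cells
(area-preserving axis ratio 0.8–1.0, radius ~ N(8, 1.5²) px truncated at
5 px — about 16 µm cells at the ~1 µm/px scale of a 10× objective with a
0.63× adapter); interior ratios uniform in [0.4, 0.7]; a 2-px halo ring at
1.15× background; touching clusters of 2–5 cells with center pull-in of at
most 30% of the smaller radius; interface pixels between touching cells at
0.85 (brighter than any interior, darker than background); dark debris
specks strictly below the 50 px filter so filter efficacy is testable by
construction; Gaussian sensor noise (sd 2 on the 8-bit scale); and a
σ = 1 px Gaussian blur standing in for defocus. Ground truth is the
pre-noise, pre-blur ellipse label grid. Fixed seeds give byte-identical
frames.

Time-lapse series draw per-field-of-view counts as Poisson realizations of
a lag → exponential → plateau expectation (defaults: N₀ = 50, 48 h lag at
40 h doubling, 10 h exponential doubling, plateau at 2000).

Limitations to keep in mind: the renderer has no optical point-spread
function, no textured in-focus morphology, no differentiated or adherent
elongated cells, no focus drift, and its cells are perfect ellipses. The
blur stands in for defocus but does not reproduce the bright wedge real
halos superpose into concave junctions, so heavily overlapping clusters
fatten slightly more in the rendered mask than in real frames. Passing the
synthetic benchmarks therefore demonstrates internal correctness of every
stage and robustness across density, illumination and clumping — not
performance on any particular instrument's data.

## Problem sizes used in validation

The shipped validation runs use: 10 frames of 768×1024 px at ~400 cells and
3 at ~1000 cells for detection accuracy; 20 random 48×48 images for
reference-equivalence of the MSER detector; 200 isolated 2–5-cell clusters
on 160×160 frames for splitting; 384×384 frames for illumination recovery;
and a 66-field, 144 h, 2.3-min-interval count series for growth analysis.
These sizes make every claim reproducible on a single CPU in minutes while
keeping each estimate's sampling error well below the margins asserted.

## Known limitations

* Frames are corrected independently; no temporal smoothing of backgrounds.
* The evaluation matcher needs a label-grid ground truth; point annotations
  are only supported through the centroid rule.
* Cells per well are counted per field of view; overlapping fields of view
  are not de-duplicated.
* The MSER sweep is exact but level-synchronous: worst-case cost grows with
  the number of populated gray levels times image area (a few seconds per
  megapixel frame), which is fine for batch work but not real-time.
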