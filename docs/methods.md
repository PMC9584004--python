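# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `charcoalscape`, in the order of the analysis pipeline.

## Coordinate and raster conventions

All coordinates are planar metres; no CRS handling or reprojection is
performed and inputs are assumed co-registered. Rasters are row-major with
the origin at the upper-left corner; the centre of cell *(row, col)* is at
*(x₀ + (col + 0.5)·c, y₀ − (row + 0.5)·c)* for cell size *c*. Nodata cells
(sentinel value, default −9999, or NaN) are excluded from every
neighbourhood statistic and propagate as nodata. ESRI ASCII grids are the
plain-text interchange format (round-trip to ~10 significant digits);
single-band GeoTIFFs written through tifffile (ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags) round-trip bit-exactly.

## Terrain covariates

* **Slope / aspect** — Horn's 3×3 weighted finite differences, the de-facto
  GIS standard; edges are handled by reflection, nodata neighbours are
  backfilled from the nearest valid cell before the window is applied.
  Slope is reported in degrees; aspect as downslope azimuth clockwise from
  north, 0 for flat cells.
* **Terrain ruggedness** — two variants are exposed because roughness
  appears twice among the environmental variables: Riley's TRI
  (√Σ(z_c−z_n)² over the 8-neighbourhood) and the standard deviation of
  elevation in a disc (default radius 5 m).
* **TPI** — centre elevation minus the mean of a surrounding disc annulus
  (centre excluded), default radius 10 m. The radius is a free parameter;
  10 m matches the platform scale of interest.
* **HLI** — the McCune–Keon heat load index on folded aspect
  |180° − |aspect − 225°||, making south-west the hottest exposure. All
  three published fits are available; the default is the third (direct)
  equation, 0.339 + 0.808·cos l·cos s − 0.196·sin l·sin s −
  0.482·cos A·sin s. Latitude must be supplied; there is no default site.
* **TWI** — ln(a / tan β) with the specific contributing area *a* from
  single-flow-direction (D8) accumulation (each cell routes to its
  steepest-descent neighbour, cells processed in decreasing elevation
  order) and tan β floored at 0.001 so flat cells stay finite. The flow
  algorithm is a documented choice; multiple-flow variants are out of
  scope.
* **Distances / kernel density** — exact KDTree distance from cell centres
  to point features; line and polygon features are densified to vertices
  at half-cell spacing first (error ≤ a quarter cell). Kernel density uses
  a Gaussian kernel normalised so the raster integrates to the point count
  on a sufficiently padded grid.

## Morphological closing

Closing = grey dilation then erosion with the same disc element. The disc
of diameter *d* contains all integer offsets with √(dx²+dy²) ≤ d/2 — the
boundary convention is inclusive, so diameter 7 has 37 pixels. Supported
diameters are odd values (5–10 px is the range of practical interest,
7 px = 3.5 m at 0.5 m cells being the default that conforms to the
smallest hearths). Borders are edge-replicated, which avoids artificial
rims at the raster edge; nodata cells are excluded from both filters.
Closing is extensive, idempotent and increasing, and on synthetic scenes
it reduces the within-platform slope variance (measured on the platform
interior beyond the disc radius, where the lip cannot bleed in).

## Seeded region growing

Seeds are local minima of the closed slope raster at or below a flatness
quantile, greedily thinned (in order of increasing value, ties by row then
column) to a minimum spacing. Regions grow on a priority queue: the
frontier 4-neighbour cell with the smallest absolute difference to the
adjoining region's running mean is attached next, until no frontier cell
is within the similarity threshold or the region reaches its area cap.
Stale queue entries are re-keyed on pop, and ties break by (row, col,
region id), so the labelling is deterministic. 4-connectivity is used
rather than 8 to prevent diagonal leakage through the lips.

Defaults — similarity threshold 8° on the closed slope, flatness quantile
0.03, seed spacing 15 m, area cap 340 m² (twice the largest expected
platform) — were calibrated once on the synthetic suite so that a
default scene yields an object population of the size used for training
in the field study (~650 objects, one third of them platforms), and then
frozen. The growth feature defaults to the closed slope alone; a
multi-layer feature distance (Euclidean over standardised layers) is
supported.

## Object features and classification

Per object × layer the 13 zonal statistics are minimum, maximum, range,
sum, mean, variance, standard deviation, Gini coefficient and the 0.05,
0.25, 0.50, 0.75, 0.95 percentiles. Variance is the population (n)
variance and percentiles use linear interpolation. The Gini denominator is
the population form 2n²x̄ (the n(n−1) sample form is available); Gini is
reported missing for layers with negative values. Perimeter counts exposed
pixel edges × cell size with no Manhattan-bias correction, and the circle
reference perimeter/area ratio for the same area is computed analytically
as 2√(π/area), so object compactness is compared against an exact circle.

Classification is a Random Forest (500 trees, √p features per split,
deterministic under a fixed seed) on the object feature table. Accuracy
assessment follows the remote-sensing convention: confusion matrix rows =
reference, columns = predicted; user's accuracy = precision (column
ratio), producer's accuracy = recall (row ratio); Cohen's
κ = (p₀−p_e)/(1−p_e). Cross-validation is stratified fivefold; metrics
are computed per fold and averaged (the pooled confusion matrix is also
reported — with equal fold sizes the two overall accuracies coincide).

## Hearth summaries

Density is hearths per hectare of a caller-supplied reference area — for
the study landscape the forested area (1600 ha) rather than the total
watershed, since that is the denominator under which 744 hearths round to
0.5 ha⁻¹; both can be reported. Elevation and slope per hearth are sampled
at the centroid cell. Pearson correlations (area vs elevation, area vs
slope) report two-sided p-values from the t approximation and are missing
for zero-variance inputs.

## Composition and interpolation

Charcoal counts and basal areas are converted to per-unit proportions by
row normalisation; zero-total rows are dropped with a warning, and merged
indistinct categories (e.g. larch/spruce charcoal, which cannot always be
separated anatomically) are carried as taxa in their own right.

IDW uses weights d⁻ᵖ (default power 2) over the 50 nearest samples (a
variable search radius), cell size 10 m. A cell within 10⁻⁹ m of a sample
returns that sample's value (exact interpolator) and predictions are
clamped to the range of the samples used, so the surface never
extrapolates. All taxa of a table are interpolated with the same neighbour
sets and weights, which preserves the cell-wise closure (proportions sum
to 1) of the interpolated surfaces. Interpolation accuracy is assessed by
leave-one-out cross-validation — the standard for deterministic
interpolators, since there is no model variance to hold out — reporting
ME, MAE, RMSE and the R² of the predicted-vs-measured regression.

The Brillouin index H = (ln N! − Σ ln nᵢ!)/N is evaluated with log-gamma.
It is defined for integer counts of a full census; continuous basal areas
are scaled (default ×10) and rounded to pseudo-counts first — an explicit,
configurable interpretation flagged as such.

## Redundancy analysis

Y (n×q responses) and X (n×p predictors) are centred and by default scaled
to unit variance — the responses mix stem counts, m² ha⁻¹, percentages and
a diversity index, so correlation-scale RDA is the sensible default. The
fitted values Ŷ = X(XᵀX)⁻¹XᵀY are decomposed by SVD; constrained
eigenvalues are s²/(n−1) and each axis is reported as a percentage of the
*total* variance of Y (not of the constrained part). Site scores are the
projections of the fitted values, response scores the SVD loadings, and
biplot scores the correlations of each predictor with the site scores.
Rank-deficient X raises an error naming the offending columns (QR with
column pivoting).

The permutation test permutes raw rows of Y (not residuals), recomputes
the sum of constrained eigenvalues, and reports
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p is never exactly zero. The
default is 999 permutations in the pipeline; 10⁴ is the study-scale
setting and remains cheap at n = 267.

## Synthetic landscape generator

The generator emulates the *structure* of the study inputs, not any
particular place. The terrain is a planar ramp (default 25°, near the
study's 27.7° mean slope) plus correlated noise (white noise smoothed by
an 8 m Gaussian, scaled to 0.35 m SD) — strong enough that seed selection
is non-trivial, smooth enough that platforms remain the flattest objects.
Platforms are ellipses (axis ratio 0.7–1, areas uniform on 20–170 m²)
levelled at the terrain elevation of their centre and blended back into
the hillslope by a linear ramp across a lip annulus 1–2 m wide; the uphill
cut and downhill fill make the lip locally steeper than the hillslope,
while laterally the lip blends into the contour — so lip steepness is
asserted on the steep sectors (75th percentile of lip-annulus slope above
the base slope), and platform flatness on the interior eroded by the
closing radius. Platforms carry centimetre-scale micro-relief (0.02 m SD,
1.5 m bandwidth), keeping interior slopes ~1–2°: real degraded platforms
are not perfectly flat, and this is precisely the variability the closing
step is there to homogenise. Features are placed by dart-throwing with
pairwise clearance; failure after bounded retries raises an error
reporting how many were placed. The default scene holds 212 platforms and
453 confusers — the sizes of the ground-validated and visually interpreted
training classes — on a 1280 m square, the smallest extent that
accommodates them comfortably.

Confusers are gullies (Gaussian-section trenches running downhill),
boulders (Gaussian humps) and terracettes (narrow partially flattened
benches along the contour, too narrow to survive the disc closing). They
are invented plumbing: their role is to give the classifier a non-RCH
class and the segmentation something to get wrong.

Charcoal sampling draws 2–6 fragments per hearth (uniform) and distributes
them multinomially over taxa; the default probabilities (pine 0.62, beech
0.15, spruce 0.08, larch/spruce-indistinct 0.13, other 0.02) mirror the
composition recorded anthracologically for the study landscape. A smooth
spatial probability field can replace the constant probabilities.

Forest plots are generated with known linear responses: two latent spatial
gradients (an elevation-like primary and an orthogonalised heat-load-like
secondary) drive the 15 environmental variables (plus independent noise),
and the 11 standardised responses are Y = X_std·B + ε with a returned
coefficient matrix B and noise SD 0.45. The loadings are chosen so the
default RDA recovers a realistic two-gradient structure (axis 1 ≈ 58%,
axis 2 ≈ 20% of total response variance, ~80% explained overall) —
comparable in magnitude to published constrained ordinations of this kind.

## What the synthetic tests do and do not show

Passing the synthetic suite demonstrates that each operation implements
its contract and that the pipeline recovers known truth under controlled
conditions. It does **not** demonstrate field-scale accuracy: the
synthetic platforms are cleaner than eroded real hearths under dense
canopy, the confusers are stylised, and the classifier's perfect synthetic
cross-validation accuracy (1.0) exceeds what mapped LiDAR data support
(~0.92 with κ ≈ 0.8 in comparable studies). Likewise, leave-one-out IDW
errors on synthetic charcoal proportions are dominated by the 2–6-fragment
multinomial noise floor (RMSE tens of percent), far above what smooth
field composition surfaces yield; the accuracy statistics are exercised,
not reproduced. Problem sizes in the test suite (300 m scenes for unit
tests, one full 1280 m scene for end-to-end recovery, 199–999
permutations) were chosen to keep the default suite fast while leaving
every statistical check adequately powered.

## Known limitations

* No CRS handling, reprojection, or LiDAR point-cloud processing — the
  DTM is the entry point.
* D8 flow routing only for TWI; no multiple-flow or pit-filling options.
* Segmentation is single-resolution and seeds only on the closed slope by
  default; hierarchical segmentation is out of scope.
* GLCM texture and spectral layers are not computed, but any co-registered
  raster added to the covariate stack is summarised identically.
* Object outlines exported to GeoJSON are convex hulls of the pixel
  centres, a deliberate simplification for interchange.
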