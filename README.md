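# charcoalscape

Detection and landscape analysis of **relic charcoal hearths** (RCHs) from
high-resolution digital terrain models, with downstream reconstruction of
historical forest composition and drivers of current forest structure.

Relic charcoal hearths are the flat circular or elliptical earthen platforms
left where charcoal kilns once stood: on a hillslope DTM they appear as
locally flat terraces (typically 20–170 m²) bounded by steep 1–2 m lips.
`charcoalscape` implements the full object-based workflow a landscape
ecologist would use to map them and read the land-use legacy they record:

1. **Terrain covariates** — slope and aspect (Horn 3×3), Riley's terrain
   ruggedness index, SD roughness, topographic position index,
   McCune–Keon heat load index, D8 topographic wetness index, Euclidean
   distance to features and Gaussian kernel density of points.
2. **Morphological enhancement** — grayscale closing of the slope raster
   with a disc structuring element (default 7 px = 3.5 m at 0.5 m cells),
   which homogenises the platform interiors before segmentation.
3. **Segmentation** — seeded region growing: seeds at local minima of the
   closed slope below a flatness quantile, priority-queue growth bounded by
   a similarity threshold and an area cap.
4. **Object features and classification** — 13 zonal statistics per object
   × layer (min, max, range, sum, mean, variance, SD, Gini, 5 percentiles)
   plus shape indices; Random Forest RCH / non-RCH classification with
   stratified fivefold cross-validation reporting user's, producer's and
   overall accuracy and Cohen's κ (rows = reference, columns = predicted).
5. **Geometry and density summaries** — area, pixel-edge perimeter,
   perimeter/area ratio against the analytic circle reference
   2·√(π/area), Pearson correlations of area with elevation and slope,
   hearths per hectare.
6. **Composition change** — charcoal fragment counts (historical) and
   basal areas (current) converted to species proportions, interpolated
   with inverse distance weighting (cell 10 m, power 2, 50 nearest
   neighbours, shared across taxa so the surfaces stay closed), assessed
   by leave-one-out ME/MAE/RMSE/R², and differenced into change maps;
   Brillouin diversity H = (ln N! − Σ ln nᵢ!)/N.
7. **Ordination** — redundancy analysis (PCA of the fitted values of the
   multivariate regression of the 11 structure/composition descriptors on
   the 15 environmental variables) with a Monte Carlo permutation test.

Because no LiDAR or field data ship with the package, a first-class
**synthetic landscape generator** produces ground-truthed inputs with the
structure the analysis assumes: dissected hillslopes with embedded flat
elliptical platforms and lip annuli, confuser landforms (gullies, boulders,
terracettes), multinomial charcoal counts (2–6 fragments per hearth) and
267-plot structure/composition tables with known linear responses to
environmental gradients. Every stage is therefore testable against known
truth.

## Worked example

```python
import numpy as np
from charcoalscape import TerrainScenario, generate_dtm, detect, PipelineConfig

scenario = TerrainScenario(seed=7)          # 212 platforms, 453 confusers
dem, truths = generate_dtm(scenario)        # 2560 x 2560 cells at 0.5 m
result = detect(dem, truths, PipelineConfig(seed=7))

print(f"objects segmented : {result.n_objects}")
print(f"CV overall accuracy: {result.report.overall_accuracy:.3f}")
print(f"CV Cohen's kappa   : {result.report.kappa:.3f}")
print(f"median footprint Jaccard: {np.median(result.rch_jaccard):.2f}")
```

prints

```
objects segmented : 667
CV overall accuracy: 1.000
CV Cohen's kappa   : 1.000
median footprint Jaccard: 0.88
```

i.e. the segmentation delineates 667 candidate objects (about a third of
them true platforms), the fivefold cross-validated Random Forest separates platforms
from background/confuser objects perfectly on this synthetic scene, and the
grown regions overlap the true platform footprints with a median Jaccard
index of 0.88. There is also a CLI for shell use
(`charcoalscape simulate|close|detect|summarise|composition|ordinate|run`).

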