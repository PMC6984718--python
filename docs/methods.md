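# Methods

`maupscale` quantifies how the modifiable areal unit problem (MAUP)
propagates through dasymetric census downscaling. A point-level
livestock census is aggregated into alternative zonation systems —
varying in **scale** (village, sub-district-like, district-like),
**zone shape** (irregular Voronoi-derived units, IRR, vs regular grids,
REG, matched by average spatial resolution) and **predictor sampling**
(one random point per polygon vs the zonal average) — and each
configuration is disaggregated back to a fine raster with a
random-forest model. The sensitivity surfaces are goodness of fit
(RMSE, Pearson's r) at the training scale and downscaling precision
(COR_down) at the finest scale.

## The downscaling model

The response of each polygon sampling unit (PSU) is

```
y_i = log10( c_i / a_i + δ )
```

where `c_i` is the additively aggregated head count, `a_i` the PSU's
*suitable* land area (km², pixel-center rule on the suitability mask)
and `δ` a density offset (default 1 bird/km²) that keeps zero-count
PSUs defined. With `δ = 0` zero-count PSUs are dropped instead; both
behaviours are supported because the treatment of log10(0) in this
family of models is conventionally left unstated.

A random-forest regression links `y` to per-PSU predictor vectors:
500 trees, `mtry = floor(√p)` candidate variables per split, fitted on
a 70 % simple random sample of PSUs and evaluated on the held-out 30 %,
repeated 20 times by default (replicate *r* uses seed `base + r`).
Pixel-level predictions are made on every suitable pixel; mean and
standard-deviation maps summarise the replicates. An optional
categorical stratum fits one forest per stratum and mosaics the
predictions; the default is a single stratum. No dasymetric
rebalancing of predictions to PSU totals is applied by default (the
evaluation concerns raw predicted densities); a `rescale_to_totals`
utility exists for users who want mass-conserving maps.

Predicted PSU values are reconstructed the same way observed ones are:
pixel predictions are back-transformed to linear densities
(`10^v − δ`, floored at 0), averaged over the PSU's suitable pixels,
and re-logged. Averaging in linear space (not mean-of-logs) keeps
observed and predicted PSU values commensurable. COR_down is the
Pearson r between these back-aggregated predictions on the *village*
(finest) tessellation and the observed village values, whatever scale
trained the model; by default all villages enter, with an option to
restrict to the held-out fold.

Degenerate correlations (a constant vector, up to floating-point
rounding of order 1e-12) return NaN rather than 0, so they cannot
silently bias replicate means. Area-stratified metrics use fixed
breakpoints per level (villages 10/20 km², sub-districts 100/200 km²,
districts 500/1000 km²); strata with fewer than 3 PSUs emit NaN rows
so the output schema is stable.

## Zonation systems

Village units are Voronoi cells of the village points clipped to the
study region — the standard surrogate where village boundary files do
not exist. Coarser irregular units are built by seeded k-way region
growing on the Voronoi adjacency graph: k seed cells are drawn, then
frontier cells attach one at a time to the adjacent partition with the
fewest members (ties broken by partition id, then cell id). This
yields contiguous, compact, strictly nested units without real
administrative shapefiles, and is fully reproducible under its seed.

The average spatial resolution of a system of n units over suitable
land area A is `ASR = √(A/n)` (km). Suitable land area — not total
polygon area — enters the formula, consistent with densities being
computed per suitable km². Regular comparators are square grids with
cell side equal to the matching irregular system's ASR, anchored at the
lower-left corner of the region's bounding box and clipped to the
region; REG systems exist only at the sub-district and district scales.
`regular_grid_zonation` drops clipped boundary cells below 5 % of
`asr²` by default (sliver densities are numerically unstable), but the
experiment pipeline builds its grids with the threshold at 0 so that
every village lies in exactly one cell and counts are conserved
exactly; sliver units without suitable pixels drop out of the response
anyway.

## Synthetic landscape

The generator emulates the statistical structure the analysis assumes,
not any real geography:

* **Predictors** — Gaussian-smoothed white noise with a configurable
  correlation length (default 10 km), standardized to mean 0, sd 1.
  Default 8 layers on a 200×200 grid of 0.5 km cells (a 100×100 km
  region).
* **Suitability mask** — an auxiliary autocorrelated field thresholded
  at the requested unsuitable fraction (default 0.25), giving
  contiguous unsuitable patches (water, protected or unpopulated land).
* **Villages** — default 2000 points uniform over suitable pixels with
  within-pixel jitter; a parent–offspring (Neyman–Scott-style) option
  produces clustered settlement patterns.
* **Counts** — negative binomial with log-mean
  `intercept + Σ β_k x_k + ε`, where `ε ~ N(0, site_noise_sd²)` is an
  unstructured log-normal village effect (default sd 1.5 on the
  natural-log scale, ≈ 0.65 dex). The site effect models the
  between-village heterogeneity a census shows but predictors cannot
  explain (husbandry practices, reporting error); because it is
  spatially unstructured it averages out under aggregation, which is
  what makes coarse-scale responses smoother than village-scale ones —
  the mechanism behind the scale effect on correlation coefficients.
  NB dispersion defaults to 1.0; the census's true count distribution
  is unknown, so the negative-binomial choice is an assumption and the
  dispersion is exposed in configuration.
* **Two regimes** — the *homogeneous* species responds weakly to two
  predictors everywhere (a backyard species raised anywhere). The
  *clustered* species is additionally gated onto high values of a focal
  habitat covariate through a soft logistic gate (sharpness 3 in
  focal-sd units, opening at the 0.6 quantile, floor 0.03), emulating a
  species concentrated in a core habitat but present at low density
  outside it. The gate was deliberately kept soft: a near-hard gate
  makes village log-densities a two-point mixture whose spread *grows*
  under aggregation, whereas real clustered censuses still show the
  narrowing of the value distribution with coarser units. With the
  defaults, the clustered species occupies strictly fewer villages and
  has a higher Gini concentration than the homogeneous one, and both
  species' log-density SD shrinks monotonically from village to
  district.
* **Exact totals** — counts are rescaled to the species' national total
  by largest-remainder rounding, so conservation checks downstream are
  exact integer identities.

Coordinates are planar km in an abstract Cartesian frame. MAUP
mechanics do not depend on a datum, and the real-data path (CSV points,
GeoJSON polygons, TIFF rasters) carries its own coordinates through
untouched. What the generator does **not** emulate: real Thai
geography, remote-sensing predictor semantics (Fourier-transformed
vegetation indices, travel times), farm-level production-system splits,
or the real census value distribution — so passing tests demonstrate
that the pipeline's mechanics and orderings behave as the theory
predicts under controlled conditions, not that any particular real
dataset would yield the same numbers.

## Experiment sizes and seeds

The default factorial is 2 species × 5 level/shape families × 2
sampling methods = 20 model families. The default fixture uses 2000
villages merged into 200 sub-district-like and 50 district-like units.
These counts keep two competing constraints satisfied: units per level
shrink roughly geometrically (10× and 4×), echoing real administrative
pyramids, while the 30 % held-out sets (600/60/15 units) stay large
enough that per-replicate Pearson correlations are meaningful at every
scale — with only a handful of district units, a 3-point correlation
estimate is pure noise. The acceptance checks run this fixture at 5
replicates; the package default is 20.

Every stage derives its seed from one master seed by fixed offsets
(landscape, mask, villages, populations, merges, then a per-family
stride for splits and forests), so a rerun with the same configuration
reproduces the sensitivity table byte for byte. Degenerate inputs are
handled explicitly: fully unsuitable PSUs are excluded from features
and response (and logged), rejection sampling for the random-point
method falls back to the zonal average after 1000 failed draws, and
village-on-boundary assignment ties break to the smallest PSU id.

## Known limitations

* Region-grown "administrative" units are compact but synthetic; real
  district shapes encode history and terrain that may interact with
  MAUP differently.
* The suitability mask is binary; partial suitability is not modelled.
* The pixel-center rule makes suitable areas exactly reproducible (and
  testable against exhaustive scans) but slightly under/over-counts
  boundary pixels relative to exact polygon–pixel intersection.
* Single-process execution; the default factorial runs in a few
  minutes on one core, and larger landscapes scale roughly linearly in
  pixels × trees.
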