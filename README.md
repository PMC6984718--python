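# maupscale

Sensitivity of random-forest census downscaling to the modifiable areal
unit problem (MAUP).

Census data usually arrive aggregated into administrative units whose
size and shape are arbitrary — and results computed from them inherit
that arbitrariness (the MAUP: a *scale* effect and a *zonation*
effect). Dasymetric downscaling pipelines such as the gridded-livestock
family disaggregate polygon-level counts to fine rasters using
environmental covariates and a random-forest model, but the influence
of the chosen aggregation units on the downscaled product is rarely
measured. `maupscale` makes that measurement routine: it aggregates a
point-level (village) census into alternative zonation systems, fits
the downscaling model on each, and reports how scale, zone shape and
predictor sampling move the quality metrics. It is aimed at spatial
epidemiologists and geographers who produce or consume downscaled
population surfaces.

## The method

For each polygon sampling unit (PSU) *i* the response is the
area-corrected log density

y_i = log10(c_i / a_i + δ),

with c_i the additively aggregated head count, a_i the suitable land
area (km²) and δ = 1 an offset keeping zero-count units defined.
A random-forest regression (500 trees, mtry = ⌊√p⌋) links y to
per-PSU predictor vectors, is trained on a 70 % random sample of PSUs
and predicts log densities on every suitable 0.5 km pixel; the split →
fit → predict cycle is replicated (20× by default) and summarised with
mean and SD maps.

The factorial design crosses:

* **scale** — village (Voronoi cells of the village points),
  sub-district-like and district-like units (seeded contiguous merges
  of the Voronoi cells, strictly nested);
* **shape** — irregular units (IRR) vs regular square grids (REG)
  whose cell side equals the ASR = √(suitable area / n units) of the
  matching IRR system (REG only at the two coarser scales);
* **sampling** — predictors read at one random suitable point per PSU
  vs averaged over the PSU's suitable pixels.

Per replicate the package reports RMSE and Pearson's r (COR) between
held-out observed and back-aggregated predicted PSU values (overall and
within PSU-area classes), and the downscaling precision COR_down: the
Pearson r between predictions aggregated to the *village* tessellation
and the observed village values, whatever scale trained the model.

A seeded synthetic-landscape module generates the study conditions:
autocorrelated predictors, a suitability mask, village points, and two
species regimes — one spatially homogeneous, one clustered on a focal
habitat covariate — with exact national totals. See
`docs/methods.md` for the model, its assumptions and the design
choices.

## Worked example

Run a small factorial (a 30×30 km landscape, 150 villages, 3
replicates) and look at the downscaling precision by training scale:

```python
from maupscale import ExperimentConfig, ModelConfig, run_sensitivity, summarize

cfg = ExperimentConfig(
    nrows=60, ncols=60, n_layers=4, n_villages=150,
    n_subdistricts=20, n_districts=8,
    model=ModelConfig(n_trees=100, n_replicates=3, seed=0),
    master_seed=42,
)
result = run_sensitivity(cfg)
summary = summarize(result.table)
cor_down = summary[(summary.metric == "COR_down") & (summary.sampling == "average")]
print(cor_down[["species", "level", "shape", "mean", "sd"]].to_string(index=False))
```

```
    species       level shape     mean       sd
  clustered    district   IRR 0.664633 0.064103
  clustered    district   REG 0.774148 0.008349
  clustered subdistrict   IRR 0.782302 0.026825
  clustered subdistrict   REG 0.793789 0.010640
  clustered     village   IRR 0.865188 0.005841
homogeneous    district   IRR 0.148322 0.064045
homogeneous    district   REG 0.176149 0.052906
homogeneous subdistrict   IRR 0.068354 0.054050
homogeneous subdistrict   REG 0.171278 0.016950
homogeneous     village   IRR 0.480548 0.042810
```

Reading the table: models trained on the finest units downscale best —
village-trained COR_down (0.87 clustered, 0.48 homogeneous) beats the
district-trained families — and the spatially clustered species is less
affected by aggregation than the homogeneous one at every scale, since
its zonal averages preserve more of the underlying spatial signal.

The same pipeline is scriptable from the shell:

```bash
maupscale simulate --nrows 200 --ncols 200 --n-villages 2000 --seed 1 --outdir out/
maupscale run-all --seed 1 --replicates 5 --outdir out/
maupscale export-maps --seed 1 --replicates 5 --bbox 20,20,60,60 --outdir maps/
```

`run-all` writes the long-format sensitivity table, replicate
summaries, zonation GeoJSONs, prediction rasters (float32 TIFF with a
JSON geometry sidecar) and a cell-status manifest.

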