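# nppkit

A raster analysis toolkit for vegetation net primary productivity (NPP):
light-use-efficiency NPP estimation, per-pixel trend and significance
mapping, weighted-centroid migration, climate partial-correlation
attribution, land-use transition accounting, and optimal-parameter
geographic-detector driver analysis — all exercised end-to-end on fully
synthetic scenarios with known, recoverable ground truth.

## What's inside

| Module | Purpose |
| --- | --- |
| `nppkit.raster` | `Grid`/`RasterCube` data model, GeoTIFF I/O (via tifffile + GeoTIFF tags), alignment, block aggregation, max-value compositing |
| `nppkit.synth` | Synthetic scenario generator: climate cubes with a prescribed NPP-driver partial-correlation structure, NDVI with prescribed per-pixel trends, latent strata explaining an exact share of response variance, exact land-use transition plans |
| `nppkit.casa` | Monthly light-use-efficiency NPP model (FPAR from NDVI and simple ratio, APAR, temperature/moisture stress, per-class maximum LUE), annual totals in TgC |
| `nppkit.trends` | Per-pixel OLS slope, Mann–Kendall S/Var/Z with tie correction, five-class trend map, productivity grades, series summaries |
| `nppkit.gravity` | NPP-weighted centroids and migration trajectories (distance + compass azimuth) |
| `nppkit.pcorr` | Pixelwise second-order partial correlation of annual NPP with precipitation/temperature/radiation, t-test significance, four-way class maps |
| `nppkit.landuse` | Land-use transition matrices, per-class mean NPP, transition-based NPP change ledger (TgC, two attribution conventions), zonal statistics |
| `nppkit.opgd` | Geographic-detector q-statistic with exact variance decomposition, five discretization methods × 3–8 partitions optimization, 90%-quantile scale selection, factor and interaction detection |
| `nppkit.pipeline` / `nppkit.cli` | Orchestration, validation regression, `nppkit` command-line interface |

## CLI

```bash
# generate a synthetic scenario (GeoTIFF layer set + ground-truth manifest)
cat > scenario.yaml <<EOF
shape: [120, 120]
year_start: 2001
year_end: 2020
seed: 1
trend_slope: 1.5
transition_plan:
- {from_class: 3, to_class: 1, area_km2: 50.0, year: 2010}
EOF
nppkit synthesize --config scenario.yaml --outdir layers/

# individual stages
nppkit casa --ndvi-dir layers --climate-dir layers --vegtype layers/vegtype.tif \
    --year-range 2001-2020 --outdir npp/
nppkit trend --annual-npp-dir npp --outdir trend/
nppkit gravity --npp-files npp/npp_annual_2001.tif --npp-files npp/npp_annual_2020.tif \
    --outdir grav/
nppkit pcorr --npp-dir npp --climate-dir layers --outdir pcorr/
nppkit landuse --lu-files layers/landuse_2001.tif --lu-files layers/landuse_2020.tif \
    --npp-files npp/npp_annual_2001.tif --npp-files npp/npp_annual_2020.tif --outdir lu/
nppkit opgd --response npp/npp_annual_2020.tif --factors factors.yaml --outdir opgd/

# or everything at once
nppkit run-all --config scenario.yaml --outdir out/
```

Rasters are single-band GeoTIFFs named `<variable>_<year>[_<month>].tif`;
tables are CSV. All grids must be in a projected metric CRS (geographic
coordinates are rejected, since distances and areas are computed planar).

## Design notes

- The temperature/moisture stress closures and the per-class maximum-LUE
  defaults follow the canonical regional calibration for this model family;
  the parameter table ships as editable CSV (`nppkit.casa.default_params`).
- The q-statistic uses population variances, so the between/within variance
  decomposition is exact; strata with fewer than 2 samples are dropped and
  logged.
- The synthetic generator is the test harness: every prescribed parameter
  (trend field, partial correlations, strata variance share, transition
  plan, signal scale) is recovered by the corresponding downstream stage
  within stated tolerances in `tests/test_acceptance.py`.
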