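# reefscape

Multiscale terrain analysis and presence-background species distribution
modelling for reef seascapes, built around bathymetric DEMs.

The package covers an end-to-end workflow:

1. **Raster core** (`reefscape.grid`) — GeoTIFF I/O, raw-depth preprocessing
   (unit conversion, single-pass 3×3 gap filling, fallback merge), reef
   cropping with a metre buffer, and Gaussian-pyramid generalisation.  Three
   source DEMs at 15/30/100 m become a nested eight-DEM stack
   (15 m → 15/30/60/120 m, 30 m → 30/60/120 m, 100 m kept as-is).
2. **Terrain attributes** (`reefscape.terrain`) — depth plus eight derived
   variables per DEM level (slope, eastness, northness, vertical/horizontal
   curvature, vector ruggedness, bathymetric position index, sky view
   factor), giving 72 predictor layers for the canonical stack, plus a
   Spearman cross-source comparison report.
3. **Vertical accuracy** (`reefscape.accuracy`) — tide correction of field
   depths to LAT, per-DEM vertical error (Δh = in-situ − DEM), and robust
   summaries (median, SD, NMAD, RMSE, 3×RMSE outliers, normal Q–Q pairs).
4. **Occurrence prep** (`reefscape.occurrence`) — thinning to one record per
   fine pixel, kernel-density-biased background sampling, and nearest-cell
   predictor extraction into a model-ready feature table.
5. **MaxEnt engine** (`reefscape.maxent`) — feature-class expansion
   (L/LQ/LP/LQP), per-feature L1 penalties scaled by a regularisation
   multiplier and the reference default per-class schedule, an exact
   penalised-logistic solver, raster/vector prediction, and FC×RM selection
   by AUC/BIC rank sums.
6. **Evaluation** (`reefscape.evaluation`) — Mann–Whitney AUC, BIC for
   sparse fits, leave-one-reef-out cross-validation in replicated background
   splits over iterations, jackknife variable importance
   (AUC_ONLY/AUC_WITHOUT/AUC_TOTAL), response curves, Kruskal–Wallis +
   Dunn/Holm group comparison with compact letter display, and
   habitat-overlap summaries by probability bin.
7. **Synthetic fixtures** (`reefscape.synth`) — seeded reef landscapes
   (lagoon–flat–crest–slope morphology plus a continuous roughness field),
   co-registered multi-resolution DEMs with sensor noise, sinusoidal tide
   tables, dive-computer-style depth records, and occurrences from a known
   logistic terrain response, so everything is testable offline.
8. **Pipeline + CLI** (`reefscape.pipeline`, `reefscape.cli`) — config-driven
   orchestration with content-hash stage caching and a JSON run manifest.

## CLI

```bash
reefscape synth --seed 7 --out fixtures/            # synthetic DEMs + records
reefscape dem build --aca fixtures/aca15.tif --dr30 fixtures/dr30.tif \
    --dr100 fixtures/dr100.tif --out dems/          # eight-DEM nested stack
reefscape terrain derive --stack dems/ --out layers/
reefscape accuracy --records fixtures/depth_records.csv \
    --tides fixtures/tides.csv --stack dems/ \
    --reefs fixtures/reefs.geojson --out accuracy.csv
reefscape sdm tune --table features.csv --out selection.csv
reefscape sdm fit --table features.csv --fc LQ --rm 2 --out model.json
reefscape eval jackknife --table features.csv --out jackknife.csv
reefscape run --config run.yaml                     # full pipeline
```

`reefscape run` takes a YAML file with `RunConfig` keys (see
`reefscape/pipeline.py`); with no DEM paths it synthesises fixtures.  Exit
codes: 0 ok, 1 config error, 2 runtime error.

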