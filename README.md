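# grasscarbon

Estimation of topsoil (0–30 cm) soil-organic-carbon density (SOCD) and
stocks for steppe and meadow grassland, as a tested, reusable pipeline:

* **pedotransfer** — four empirical exponential BD(SOC) models
  (`BD = c + a·exp(−b·SOC)`) with forward evaluation and closed-form
  inversion, explicit out-of-domain policies, SOM↔SOC conversion in both
  printed and van Bemmelen directions, plus the titration (SOM) and
  cylinder-core (BD) laboratory data reductions.
* **profiles** — per-layer and total 0–30 cm SOCD via the depth-weighted,
  gravel-corrected integral `Σ Tᵢ·BDᵢ·SOCᵢ·(1 − Cᵢ/100)/100`
  (kg C·m⁻²), with re-slicing of arbitrary profile layering onto the
  fixed 0 / 9.1 / 16.6 / 30 cm scheme and batch tables per estimation
  method (measured SOC, BD-model inversion 1–4, SOM conversion).
* **ndvi** — annual maximum-value compositing, nodata-aware block-mean
  aggregation (e.g. 1 km → 10 km), and the per-type affine NDVI→SOCD
  transfer (steppe `20.201·NDVI − 0.9206`, meadow `17.846·NDVI + 0.0155`)
  with negative-value clamping and a ≥0.8 saturation flag.
* **trends** — per-pixel and regional trend statistics: closed-form
  least-squares slope, Mann–Kendall S/Z with tie-corrected variance and
  continuity correction (three-way significance at 1.96), Sen's median
  pairwise slope, and the five-level slope classification
  (boundaries −0.1 / −0.01 / 0.01 / 0.1) with class-area percentage
  tables by grassland type.
* **stocks** — zonal SOC storage (Σ SOCD × pixel area, reported in
  10¹⁰ kg) by grassland type and layer, plus IDW / ordinary-kriging
  interpolation of point SOCD to grids (both exact at sample sites).
* **correlation** — Pearson screening of SOCD against biomass, soil
  moisture/temperature/conductivity and elevation with two-level
  (p<0.01 / p<0.05) significance flags and pairwise deletion.
* **synthetic** — seeded generators for every input (grassland mask,
  NDVI stacks with planted per-pixel trends, three-layer soil profiles
  consistent with a chosen forward pedotransfer model, plot surveys with
  a target correlation matrix), each returning its ground truth;
  byte-identical outputs for a fixed seed.

Rasters are carried as plain-text ESRI ASCII grids (`.asc`), tables as
CSV — everything is text and self-contained; no external datasets are
needed.

## CLI

```sh
# write a self-contained synthetic fixture (mask, NDVI years, profiles,
# surveys, truth grids)
grasscarbon simulate --out fixture/ --seed 1

# profile-based SOCD per method (measured | 1..4 | som)
grasscarbon profile-socd --profiles fixture/profiles.csv --model 1 \
    --out socd_bd1.csv --qc-out qc.jsonl

# NDVI composites -> SOCD surface
grasscarbon ndvi-socd --ndvi fixture/ndvi_2005.asc \
    --mask fixture/mask.asc --out socd_2005.asc

# per-pixel trend analysis over a directory of annual SOCD grids
grasscarbon trend --stack socd_dir/ --mask fixture/mask.asc --out-prefix trend

# zonal storage accounting (10^10 kg)
grasscarbon stocks --socd socd_2005.asc --mask fixture/mask.asc \
    --cell-area auto --out stocks.csv

# driver screening
grasscarbon correlate --surveys fixture/surveys.csv --out corr.csv
```

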