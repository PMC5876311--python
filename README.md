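# vitalcentiles

Age-smooth centile and z-score reference models for pediatric emergency-department
vital signs (heart rate and respiratory rate), built on four-parameter
Box–Cox distribution families fitted as smooth functions of age.

The package implements the full reference-interval pipeline:

| Module | What it does |
| --- | --- |
| `vitalcentiles.distributions` | BCPE (Box–Cox power exponential) and BCT (Box–Cox *t*) families: density, CDF, quantile, z-score, sampling, and inverse fitting of the four parameters (μ, σ, ν, τ) from centile points |
| `vitalcentiles.cleaning` | Measurement-level cleaning: simultaneous-duplicate averaging (10% HR/RR, 3% TMP range rule), the 15-minute initial-triple rule, implausible-value and trauma/chronic-flag exclusions, with a per-encounter exclusion log |
| `vitalcentiles.gamlss` | GAMLSS-style fitting: each of μ, σ, ν, τ a penalized cubic B-spline of power-transformed age, cyclic-backfitting maximization of the penalized likelihood, SBC-driven selection of the age power ζ and smoothing (effective df), RR dither + log preprocessing |
| `vitalcentiles.tables` | Reference deliverables: 40-age × 11-centile tables (C1…C99) and 40 × 13 z-score tables (−3.0 … +3.0 SD), plus the single-value z-score lookup |
| `vitalcentiles.validation` | Stratified 2/3 : 1/3 split-sample validation with tail-coverage counting, Pearson chi-square (df = 1) or Fisher comparison, Holm step-down adjustment, and with/without-exclusion sensitivity comparison |
| `vitalcentiles.synthetic` | Synthetic cohort generator anchored to the published 40-row HR/RR centile tables shipped in `vitalcentiles/data/` (per-age BCPE HR, log-scale BCT RR, published age mix, RR digit preference, duplicates, outliers, exclusion flags) |

## CLI

The console script `vitalcentiles` chains the whole pipeline:

```bash
# 1. generate a synthetic cohort (no external data needed)
vitalcentiles simulate --n 200000 --seed 1

# 2. clean it (writes clean_observations.csv + exclusion_log.csv)
vitalcentiles clean

# 3. fit the smooth four-parameter model per vital
vitalcentiles fit --vital hr --zeta 0.3 --model-out hr_model.json
vitalcentiles fit --vital rr --seed 1 --model-out rr_model.json   # dithered + log scale

# 4. emit the reference tables
vitalcentiles tables --model hr_model.json \
    --centile-out hr_centiles.csv --zscore-out hr_zscores.csv

# 5. split-sample validation (Holm-adjusted report, Table-3 layout)
vitalcentiles validate --vital hr --seed 2

# 6. screening-tool lookup
vitalcentiles zscore --model hr_model.json --age 2.5 --value 126
```

Omitting `--zeta` in `fit` runs the full SBC grid search over the age
power and per-parameter effective-df grids (slower).

## Notes

* The published 40-row HR/RR centile tables and per-age cohort counts in
  `src/vitalcentiles/data/` are the anchor for the synthetic generator; the
  original ~1.2M-record source database is proprietary and not included.
* Model files are self-describing JSON (`vitalcentiles-model-v1`) holding
  family, log-scale flag, ζ, knots, spline coefficients, effective df and
  the dither seed.
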