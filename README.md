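# epiage

Uncertainty-aware DNA-methylation age clocks from bisulfite amplicon read
counts.

`epiage` builds epigenetic age-prediction models for populations where no
known-age individuals exist. Instead of point ages, each sample carries a
confidence-weighted skew-normal age probability distribution derived from
catalogue estimates (Age_best, Age_min, Age_max and a confidence rating),
and each methylation estimate carries its binomial read-count uncertainty.
Both sources of uncertainty are propagated by resampling into per-sample
predicted-age distributions with 95% highest-density intervals.

## Pipeline

1. **Quantification** (`epiage.methyl`) — per-site A/C/G/T read counts at
   CpG and non-CpG cytosine sites become a QC-filtered methylation matrix:
   corrected coverage `K = n_C + n_T`, per-sample bisulfite conversion
   efficiency from non-CpG cytosines, conversion-efficiency-corrected
   methylation probabilities (with a half-lowest-per-locus substitution for
   non-positive values), on the logit scale.
2. **Age priors** (`epiage.age_prior`) — a skew-normal is fitted per sample
   so its mode equals Age_best and its 0.025/0.975 quantiles equal
   Age_min/Age_max, then mixed with a Uniform(Age_min, Age_max) using
   weights 0.2 / 0.55 / 0.75 / 1.0 for confidence ratings 2–5.
3. **Model search** (`epiage.clocks`, `epiage.site_selection`,
   `epiage.search`) — a design grid over training method (elastic net,
   random forest, RBF support-vector regression, additive spline model),
   optional log-age transform, stepwise CpG-site selection (elastic-net
   inclusion frequency or random-forest permutation importance), training
   sample subset (All / CR3+ / CR4+) and CR weighting. Models are scored
   by leave-one-out (out-of-bag for random forests) median absolute error
   on high-confidence samples, overall and within age bins 0–9 / 10–24 /
   25+ years.
4. **Uncertainty propagation** (`epiage.uncertainty`) — replicates redraw
   each sample's age from its prior and each methylation count from
   `Binomial(K, n/K)`, refit the clock and predict every sample (clamped
   to [0, 80] years). Draws are summarised by 95% HDIs, Age_best coverage
   and longitudinal pair ordinality.

`epiage.simulate` generates synthetic cohorts (read counts, true ages and
degraded catalogue age records) with the same statistical structure, so the
entire pipeline is testable offline.

## Command-line usage

```bash
# generate a synthetic cohort
epiage simulate --config config.yaml --seed 1 --out sim/

# counts -> filtered logit methylation matrix + QC report
epiage quantify sim/counts.tsv --out quant/

# fit the confidence-weighted skew-normal age priors
epiage fit-priors sim/ages.tsv --out priors/

# stepwise site selection (audit table)
epiage select-sites quant/ sim/ages.tsv --method ENR --reps 1000 --out sel/

# evaluate the design grid and rank models
epiage search quant/ sim/ages.tsv --config config.yaml --seed 1 --out search/

# train one configured clock, then propagate uncertainty
epiage train quant/ sim/ages.tsv --config config.yaml --out clock/
epiage resample quant/ sim/ages.tsv clock/clock.pkl --reps 1000 --seed 1 \
    --save-draws --out resample/
epiage report resample/ --out figures/
```

The YAML config holds QC thresholds (`qc:`), tuning settings (`tuning:`,
plus `desk_scale: true` for reduced grids), the design grid (`grid:`), the
clock to train (`model:`) and synthetic-cohort parameters (`synth:`).
Defaults match the reference analysis (QC thresholds 1000/1000/100 reads,
1000 replicates, 10 000 trees, alpha in [1e-4, 0.5], prediction bounds
[0, 80] years). Every command writes a manifest with inputs, seed and a
config hash.

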