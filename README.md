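# ivmr

Two-sample summary-data Mendelian randomization (MR) in Python:
estimators, diagnostics, sensitivity procedures, a power calculator, and
a seeded synthetic summary-statistics generator so the whole stack is
testable offline.

## What's inside

- **`ivmr.data`** — `SummaryAssociation` / `HarmonizedInstrumentSet`
  data model, delimited-text readers with configurable column maps,
  allele harmonization (swap detection, strand complementation,
  palindromic-SNP policies with frequency inference), exposure-unit
  rescaling, per-SNP provenance logging.
- **`ivmr.estimators`** — Wald ratios (first/second-order SEs),
  inverse-variance-weighted meta-analysis (fixed / multiplicative
  random-effects / auto) with Cochran's Q, weighted-median estimator
  with parametric-bootstrap SE, MR-Egger regression with the intercept
  pleiotropy test, the I2GX instrument-strength statistic, and SIMEX
  dilution correction of the Egger slope (quadratic extrapolation,
  difference-based variance).
- **`ivmr.hetpen`** — heterogeneity-penalized model averaging over all
  instrument subsets (consistent under plurality validity), with a
  level-set confidence region that may be disjoint.
- **`ivmr.presso`** — MR-PRESSO global RSS test, per-SNP outlier test
  (Bonferroni-adjusted, add-one p-values), and distortion test.
- **`ivmr.sensitivity`** — leave-one-out and named-exclusion
  reanalysis, Bonferroni thresholds, noncentrality-based binary-outcome
  power.
- **`ivmr.simulate`** — generator of two-sample summary statistics with
  configurable causal effect, instrument strength split, balanced or
  directional pleiotropy, and planted outliers; bit-reproducible.
- **`ivmr.pipeline` / `ivmr.cli`** — multi-outcome orchestration with a
  tidy results TSV, run log, and optional forest plot.

## CLI

```sh
# synthetic study: exposure.tsv, outcome.tsv, truth.json
ivmr simulate --n-snps 8 --theta -0.3 --seed 7 --out sim/

# run estimators against one or more outcomes
ivmr estimate --exposure sim/exposure.tsv \
    --outcome sim/outcome.tsv:all-IS \
    --methods ivw,wm,egger,simex,hetpen,presso,loo \
    --scale 0.1 --seed 1 --out results/

# power across candidate odds ratios
ivmr power --n-total 438847 --n-cases 34217 --r2 0.016
```

`ivmr estimate` also accepts a YAML config (`--config cfg.yaml`)
mirroring the flags. Input files are delimited text with a header; the
default column names are `rsid, effect_allele, other_allele, eaf, beta,
se, pval, n` and can be remapped via the config `column_map`.

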