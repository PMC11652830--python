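# mrmediate

Two-sample Mendelian randomisation (MR) mediation analysis on GWAS summary
statistics: instrument selection, allele harmonisation, univariable and
multivariable MR estimation, sensitivity diagnostics, and two-step mediation
with delta-method confidence intervals. Everything runs on plain delimited
summary-statistics text and ships with a synthetic-data generator, so no
external download is ever required.

## What it does

- **`sumstats`** — read/write delimited GWAS summary statistics, harmonise
  effect alleles across datasets (swap → sign flip, strand complementation,
  palindromic-variant handling via allele frequency), convert log-odds to
  odds ratios.
- **`instruments`** — select instruments by significance threshold
  (default `p < 5e-8`), greedy LD clumping (`r² < 0.001`, 10,000 kb window)
  against a user-supplied or identity LD matrix, and the weak-instrument
  filter `F = (β/se)² > 10`.
- **`estimators`** — Wald ratio, fixed/multiplicative-random-effects IVW,
  MR-Egger (slope + intercept pleiotropy test), and the weighted median with
  a seeded parametric bootstrap SE.
- **`sensitivity`** — Cochran's Q, leave-one-out influence analysis, and
  MR-PRESSO (simulation-based global test, per-variant outlier detection
  with Bonferroni correction, outlier-corrected IVW, optional distortion
  test).
- **`mvmr`** — multivariable IVW (joint direct effects of several exposures)
  with heterogeneity and multivariable Egger-intercept diagnostics.
- **`mediation`** — product-of-coefficients indirect effects, first-order
  delta-method SEs/CIs, signed proportion mediated, and assembly of a
  two-step decomposition (total / direct / indirect).
- **`simulate`** — three-trait summary statistics under a linear structural
  model exposure → mediator → outcome with configurable true effects,
  pleiotropy (balanced/directional), planted outliers, and a truth ledger
  for parameter-recovery tests; plus a canonical named fixture suite.
- **`pipeline`** — orchestrates bidirectional univariable MR and the
  two-step design (univariable MR → MVMR → mediation, with a significance
  gate on the mediator's MVMR coefficient), writing results tables, a run
  log and a JSON manifest with thresholds, seeds and input hashes.

## CLI

```sh
# synthetic three-trait dataset with known truth
mrmediate simulate --seed 42 --a 0.4 --b 0.5 --c-prime 0.1 --out sim/

# univariable MR with sensitivity analyses (optionally --bidirectional)
mrmediate univariable --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --seed 1 --out run_uni/

# two-step MR mediation
mrmediate two-step --exposure sim/exposure.tsv --mediator sim/mediator.tsv \
    --outcome sim/outcome.tsv --seed 1 --out run_med/

# canonical named test fixtures
mrmediate fixtures --out fixtures/
```

All commands also accept `--config run.yaml` (blocks: `datasets`,
`thresholds`, `estimators`, `sensitivity`, `mediation`, `seed`,
`bidirectional`); explicit flags override the file. Threshold flags:
`--p-threshold`, `--clump-r2`, `--clump-kb`, `--f-min`.

Summary-statistics files are tab- or comma-delimited with a header; columns
`variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n`
(a `column_map` in the config adapts other layouts). An LD matrix, when
supplied, is a tab-delimited square r² matrix with variant ids as the header
row/column; without one, variants are treated as independent.

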