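# crossmqtl

Cross-ancestry *cis*-mQTL analysis toolkit. Implements a complete,
reproducible pipeline for comparing the genetic control of DNA methylation
between two populations (labelled EUR and EAS throughout), exercisable
end-to-end on a bundled two-population synthetic-data generator with known
ground truth — no external downloads required.

## What it does

- **`synthdata`** — two-population genotype panels (Balding–Nichols
  allele-frequency divergence, population-specific LD blocks from a
  thresholded AR(1) latent Gaussian), methylation phenotypes with
  cross-population-correlated causal effects, covariate/batch structure,
  and plain-text output (VCF / TSV / JSON truth).
- **`preprocess`** — genotype QC (missingness > 5%, exact Hardy–Weinberg
  p < 1e-6, MAF < 1%, info < 0.8), covariate residualization, and
  rank-based inverse-normal transformation (Blom offset).
- **`assoc`** — per-cohort cis-window scans (±1 Mb, OLS with t-tests),
  lead-SNP extraction with deterministic tie-breaks, allele harmonization,
  and fixed-effects inverse-variance-weighted meta-analysis.
- **`rb`** — correlation of QTL effect sizes between datasets corrected for
  estimation error (method-of-moments with delete-one jackknife SEs), with
  discovery-only lead-SNP ascertainment to avoid winner's-curse bias.
- **`ld`** — reference-panel dosage r², LD blocks (r² > 0.8 to an anchor),
  and block-overlap tests.
- **`classify`** — stringent / ancestry-specific set definitions
  (p < 1e-10 / p > 1e-6 with same-lead and alternate-cohort exclusions),
  the hierarchical sharing classification (same lead → strong LD → block
  overlap → conditional-signal match → conditional block overlap →
  unexplained), tally/report formatters, and allele-frequency heterogeneity
  summaries.
- **`cojo`** — stepwise approximate conditional analysis from summary
  statistics and reference LD (standardized z-score formulation,
  ridge-stabilized, collinearity-capped).
- **`finemap`** — single-causal-variant fine mapping via Wakefield
  approximate Bayes factors averaged over a prior-variance grid, 95%
  credible sets, cross-ancestry fine mapping (product of per-population
  Bayes factors), 3-IQR outlier filtering, and a sample-size-versus-
  resolution simulation experiment.
- **`smr`** — summary-based Mendelian randomization (chi-square(1) SMR
  statistic, delta-method SEs) with the HEIDI heterogeneity filter
  (Satterthwaite-matched correlated chi-square sum).
- **`cli` / `pipeline`** — YAML-configured orchestration of all stages with
  deterministic, seed-stamped TSV/JSON reports.

## CLI

```bash
crossmqtl init-config config.yaml     # write the default configuration
crossmqtl all --config config.yaml --outdir out/   # full pipeline
crossmqtl simulate --seed 7 --outdir out/          # just the data
crossmqtl meta --config config.yaml --outdir out/  # pipeline through meta-analysis
```

Verbs: `simulate qc scan meta rb classify cojo finemap simsize smr all`.
Each verb runs the pipeline through its stage; disabling a stage in the
config makes dependent stages fail with an explicit message. Every output
file header carries the seed and a config hash, and identical
(config, seed) pairs reproduce outputs byte-for-byte.

## Layout

```
src/crossmqtl/      one module per pipeline stage (see above)
tests/              pytest suite: unit + property + acceptance criteria
scripts/acceptance.py
```
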