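# mrscreen

A two-sample Mendelian randomization (MR) screening toolkit for
phenome-wide analyses on GWAS summary statistics. It implements the full
pipeline of a bidirectional screen against a single focal outcome:

- **`mrscreen.gwas_data`** — summary-statistics I/O with per-row
  validation, allele harmonization (sign flips, palindromic-SNP policy),
  LD references (dense matrix or triplet format), and rescaling of
  linear-model betas on binary traits to the log-odds scale via
  `1/(mu*(1-mu))`.
- **`mrscreen.instruments`** — greedy LD clumping, LD-proxy substitution,
  cis-window instrument selection for protein traits, per-variant variance
  explained, Steiger directionality filtering, and F statistics.
- **`mrscreen.estimators`** — Wald ratio, inverse-variance weighted (IVW)
  with multiplicative random-effects inflation, MR-Egger, weighted median,
  and simple/weighted mode estimators with parametric-bootstrap SEs, plus
  a driver that adds IVW on the Steiger-filtered subset (six results).
- **`mrscreen.mvmr`** — multivariable MR direct effects, conditional F
  statistics, and a staged (category → pooled → refit) model builder.
- **`mrscreen.coloc`** — Bayesian colocalization via per-SNP approximate
  Bayes factors, computed entirely in log space (PP H0..H4).
- **`mrscreen.screen`** — the orchestration layer: eligibility filtering,
  Bonferroni thresholds, the three-stage robustness verdict, forward /
  reverse screens and the cis-protein arm with colocalization.
- **`mrscreen.simulate`** — synthetic two-sample GWAS generators (known
  causal effect, pleiotropy modes, LD regions, binary-linear traits, full
  phenomes with a ground-truth ledger) so every stage is testable offline.

## CLI

```sh
# write a 100-trait synthetic phenome (TSV tables + truth ledger + LD files)
mrscreen simulate scratch/phenome --n-traits 100 --seed 1

# clump one trait's summary statistics
mrscreen clump scratch/phenome/trait_001.tsv --p1 5e-8 --r2 0.001 --kb 10000

# univariable MR (all six methods)
mrscreen mr scratch/phenome/trait_001.tsv scratch/phenome/outcome.tsv --seed 1

# phenome-wide forward screen with the three-stage verdict
mrscreen screen-forward scratch/phenome --seed 1 --out-prefix scratch/fw

# reverse screen, protein arm, colocalization, multivariable MR
mrscreen screen-reverse scratch/phenome --exposure-id outcome --out-prefix scratch/rv
mrscreen screen-proteins scratch/phenome --out-prefix scratch/pr
mrscreen coloc region_x.tsv region_y.tsv
mrscreen mvmr outcome.tsv --exposure bmi=bmi.tsv --exposure height=height.tsv
```

Summary-statistics files are tab-delimited with the common GWAS headers
(`SNP CHR BP EA OA EAF BETA SE P N NCASE NCONTROL`); a custom column map can
be supplied programmatically. Screens accept a YAML config covering every
threshold (`ScreenConfig` fields).

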