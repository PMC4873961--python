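# cmodel

A case-mix-adjusted reference for caesarean section (CS) rates at health
facilities, as a tested Python library and CLI:

- **Robson ten-group classification** (`cmodel.robson`) — exhaustive,
  mutually exclusive classification of deliveries with a group-wise CS-rate
  table (group sizes, rates, relative sizes, contributions).
- **Four fixed logistic scoring models** (`cmodel.core`) — versions
  v1.0–v1.3, nested by data availability, computing each woman's probability
  of caesarean section from up to 14 encoded covariates.
- **Benchmarking** (`cmodel.benchmark`) — observed vs expected CS rate over
  the identical record subset, standardised CS ratio (SCR), a configurable
  ±20% uncertainty range, and per-Robson-group reports.
- **Validation statistics** (`cmodel.validation`) — rank-based ROC/AUC with
  Hanley–McNeil standard errors, Youden-J cut-offs, classification tables
  with the diagnostic odds ratio, quintile calibration, and
  DerSimonian–Laird random-effects meta-analysis of AUCs.
- **Reference-population construction** (`cmodel.refpop`) — facility outcome
  indicators (CS rate, intrapartum-related perinatal mortality, maternal
  mortality, near-miss and severe-outcome rates), double-median facility
  selection, a seeded 90/10 split, and a from-scratch IRLS logistic fitter
  for coefficient-recovery work.
- **Synthetic data** (`cmodel.simulate`) — multi-facility obstetric datasets
  generated from the shipped models with configurable covariate prevalences,
  plus deterministic named fixtures.
- **Record I/O** (`cmodel.records`) — a per-woman CSV schema with explicit
  missingness, synonym-tolerant enumeration parsing, total (never-crashing)
  parsing, and an invariant-checking validation report.

## CLI

All commands are subcommands of `cmodel`; `--config` takes a YAML mapping
from source column names to canonical field names when your CSV headers
differ from the defaults (see `cmodel.records.FIELD_ORDER`).

```bash
# generate synthetic data with known truth
cmodel simulate --seed 7 --n-facilities 5 --n-per-facility 2000 --out sim.csv

# Robson table
cmodel robson --in sim.csv --out robson.json --text

# per-record CS probabilities (version auto-selected from available columns)
cmodel predict --in sim.csv --version auto --out probs.csv

# one woman, mirroring an interactive calculator
cmodel predict-one --parity 0 --previous-cs 0 --onset spontaneous \
    --presentation cephalic --gestational-age 40 --version v1.0

# observed vs expected CS rate with the standardised CS ratio
cmodel benchmark --in sim.csv --out report.json --range 0.20
cmodel benchmark --in sim.csv --by-robson-group --out groups.json
cmodel benchmark --in sim.csv --all-versions --out all.json

# discrimination + calibration pipeline, and AUC meta-analysis
cmodel validate --in sim.csv --out validation.json
cmodel meta --in aucs.csv --out meta.json        # columns: study_id,auc,se

# reference-population workflow
cmodel build-reference --in sim.csv --out refpop.csv \
    --report thresholds.json --seed 17
cmodel refit --in refpop_a1.csv --version v1.0 --out coefficients.json
```

## Assumptions worth knowing

- **Maternal-age cut-off.** The published coefficient table gives a single
  0/1 rule for maternal age without stating the threshold; this package
  defaults to ≥ 35 years (advanced maternal age) and exposes `--age-cutoff`
  everywhere.
- **Parity indicator direction.** x1 = 1 for multiparous women (parity ≥ 1),
  which is the direction consistent with the negative parity coefficient and
  the lower CS rates of multiparous Robson groups.
- **Fitting.** The refit path uses fixed-effects maximum-likelihood logistic
  regression (IRLS), not a random-intercept model; an optional
  facility-level cluster bootstrap provides clustering-aware standard
  errors. This is a documented simplification: the target of the fitter is
  coefficient recovery, not variance-component estimation.
- **Synthetic data.** Covariates are drawn independently apart from two
  enforced consistency constraints (previous CS only for multiparous women;
  prelabour-CS onset only with caesarean mode); no joint covariate
  distribution is claimed.
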