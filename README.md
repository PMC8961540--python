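# glycorisk

Compositional analysis of the serum N-glycome as a biomarker of alcohol
risk drinking. The package implements the full analysis pipeline as tested,
reusable components:

- **`glycorisk.synthetic`** — synthetic cohort generator: per (sex × risk)
  stratum, a 46-peak compositional glycome (log-normal with optional
  one-factor correlation, closed to 100%), covariates (age, smoking,
  alcohol g/week with label-consistent resampling against the sex-specific
  risk-drinking definition), and standard markers (GGT, MCV, CDT) matched to
  published stratum medians/IQRs. Also serves the six exact published 2×2
  marker contingency tables (`table2_fixtures`).
- **`glycorisk.calibration`** — chromatogram reduction: fifth-order
  polynomial dextran-ladder calibration (retention time → glucose units),
  binning into 46 contiguous half-open GU windows, closure to % total area.
- **`glycorisk.traits`** — derived glycan traits (sialylation S0–S4,
  galactosylation G0–G4, branching A1–A4, oligomannose, core/outer-arm
  fucosylation) as a data-driven coefficient table with fractional peak
  splits; three exact partition identities hold by construction.
- **`glycorisk.stats`** — Mann–Whitney rank-sum (exact ≤ 20 obs without
  ties), Pearson chi-squared, Jonckheere–Terpstra trend test (normal
  approximation with a seeded permutation fallback under heavy ties), and
  Holm step-down ("sequential Bonferroni") adjustment.
- **`glycorisk.balance`** — selbal-style forward selection of log-contrast
  balances predicting a binary outcome with covariate adjustment: exhaustive
  best pair, greedy growth, repeated stratified k-fold CV for model size;
  fully seed-reproducible with lexicographic tie-breaking.
- **`glycorisk.diagnostics`** — marker threshold rules, 2×2 diagnostic
  metrics (sensitivity/specificity/LR+ with log-method 95% CI), ROC/AUC with
  DeLong CIs, and covariate-adjusted marker-vs-balance comparisons.
- **`glycorisk.pipeline` / `glycorisk.cli`** — config-driven orchestration
  with provenance (seed + config hash in every output).

## CLI

```bash
# synthetic cohort CSV (both sexes, 500 subjects per stratum)
glycorisk simulate --sex both --n 500 --seed 1 --out cohort.csv

# full pipeline from a YAML config
glycorisk analyze --config run.yaml
glycorisk report --run-dir runs/latest

# chromatogram -> closed 46-peak table
glycorisk reduce-chromatogram --peaks peaks.csv --ladder ladder.csv --out gp.csv
```

Minimal `run.yaml`:

```yaml
mode: simulate        # or: ingest (+ input_path: cohort.csv)
seed: 1
n_per_stratum: 500
sexes: [M, F]
output_dir: runs/latest
```

Per sex the run directory contains a univariate peak screen with Holm
adjustment, a derived-trait comparison table, the selected balance (JSON +
per-subject scores), diagnostic-marker metrics with adjusted ROC/AUC, and a
manifest with seed, config hash and versions.

## Notes

- GU window boundaries of the 46-peak scheme are not published; the default
  table (46 equal windows on GU 4.4–12.0) is an explicitly flagged
  placeholder and fully configurable.
- The synthetic generator's joint distribution (log-normal, one-factor
  correlation with loading 0.3) is an artifact choice to give downstream
  methods realistic correlation structure, not a claim about any real
  cohort.
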