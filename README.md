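# cardiopsych

Reusable analysis chain linking subtle ECG/HRV features to psychological
assessment scores (PCL-5, PHQ-9, Beck Anxiety, and an ordinal 1–4 clinical
conclusion):

1. **`cardiopsych.synth`** — synthetic RR series, 6-lead limb ECG records
   (sum-of-Gaussians beat template with analytic ground-truth fiducials;
   leads III/aVR/aVL/aVF derived by limb-lead algebra), and cohort tables
   with planted linear signal, collinear pairs, outliers and missing cells —
   with the true population R² reported alongside.
2. **`cardiopsych.features`** — R-peak detection (band-pass + squared
   derivative envelope + adaptive threshold), median-beat wave delineation
   (5 % threshold crossing), amplitude/duration/area measurement, derived
   ratios (Q/R, R/P, R/T, P/QRS area, Macruz index, QTcF), and HRV metrics
   (SDNN/RMSSD/SDSD/pNN50, Welch LF/HF, DFA α1, Baevsky stress index,
   Mashin index, coherence ratio).
3. **`cardiopsych.scoring`** — the hierarchical norm-anchored scoring
   system: piecewise-linear mapping of each parameter onto a 0–100 point
   scale (100 at the mean, 75 at M ± σ, 0 at the extreme bounds), four-level
   averaging hierarchy (parameters → groups → blocks → integral indicator),
   plus Huber-robustness and HDBSCAN-homogeneity diagnostics. A norm table
   (CSV) and hierarchy (YAML) ship with the package and are user-replaceable.
4. **`cardiopsych.association`** — Pearson/Spearman screening of every
   feature against every target with tiered significance summaries
   (p < 0.001 / 0.01 / 0.05 / 0.1, exclusive bins plus cumulative counts).
5. **`cardiopsych.selection`** — nested forward feature selection:
   stratified train/test split, training-only isolation-forest outlier
   removal, train-median imputation, |r| > 0.7 collinearity filter,
   feature/target transformer grid (none / quantile / Yeo-Johnson ×
   none / Box-Cox / Yeo-Johnson), stepwise forward selection with 5-fold CV
   OLS, a one-standard-error rule for the model size, and a single held-out
   evaluation.
6. **`cardiopsych.cli`** — subcommands `simulate`, `extract`, `score`,
   `screen`, `select`, `run-all`, `validate-norms`.

## CLI

```bash
# synthetic end-to-end run: cohort -> screening -> selection -> report
cardiopsych run-all --mode synthetic --seed 7 --out out/

# your own feature table (CSV: subject id column + feature columns)
cardiopsych run-all --mode feature-csv --features f.csv --targets t.csv \
    --target beck --seed 7 --out out/

# a directory of signal CSVs (<id>_ecg.csv, optional <id>_rr.csv)
cardiopsych extract --signals signals/ --out features.csv
cardiopsych score --features features.csv --out scored.csv
cardiopsych validate-norms my_norms.csv
```

Signals use a plain CSV dialect (`time_s` column + one column per lead, µV);
RR series are single-column CSVs in ms. Every run is deterministic in
`--seed` (each stage draws from a named substream), and reports are stamped
with the seed and package version. An optional YAML `--config` overrides the
cohort and selection blocks; see `tests/test_cli.py` for a worked example.

Outputs per run: ranked correlation tables and tier summaries per target and
method, outlier bookkeeping (total / detected / processed), the transformer
grid with CV scores, the top selected features with coefficients, and a
machine-readable `report.json`.

## Acceptance

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

No numeric acceptance targets are defined for this artifact (the original
cohort behind the published reference values is not publicly deposited), so
acceptance is property-based: `tests/test_acceptance.py` implements eight
criteria
(metric oracles to 1e-12, hand-computed worked examples, noiseless signal
recovery within 2 % / 10 ms, DFA calibration on white and pink noise,
null-cohort screening calibration, planted-signal selection recovery at
n = 90, leakage guards, and structural invariants including byte-identical
reruns). The script runs a fast end-to-end self-check and writes `{}`.
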