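# cvrisk

Ten-year cardiovascular risk equations, intercept-level recalibration and a
calibration/discrimination evaluation pipeline.

The package implements two closed-form risk equations — the pooled-cohort
ASCVD equation (sex-stratified, proportional-hazards form
`risk = 1 − s0₁₀^exp(LP − mean LP)`, white strata) and the European
cardiovascular-mortality score (cause-specific Weibull baseline survival for
CHD and non-CHD causes, low-risk country variant) — together with:

* **cohort I/O** — a delimited-text cohort format, unit conversion
  (mg/dL ↔ mmol/L at 38.67), eligibility filters (age 40–79, prevalent
  CHF/MI/stroke, completeness) with deterministic exclusion accounting, and
  administrative censoring at the 10-year horizon;
* **recalibration** — the "calibration in the large" correction
  `c = ln[(O/(1−O)) / (P̄/(1−P̄))]`, applied by default as a logit shift of
  predicted risk (an exponent-shift mode is available), plus event-stratified
  k-fold cross-validation of the recalibrated score;
* **evaluation** — observed event frequency (crude or Kaplan–Meier
  adjusted), incidence rates per 1,000 person-years, overestimation
  percentages, decile calibration tables, Harrell's C for censored data with
  a seeded bootstrap CI, and ROC/AUC export;
* **simulation** — synthetic cohorts matching configurable marginal
  summaries (truncated-normal age; log-normal lipids/blood-pressure fitted to
  median and IQR; Bernoulli binaries) with a known event-generating model,
  including presets that emulate two published German population cohorts;
* **a CLI** (`cvrisk`) chaining all of the above.

## CLI

```bash
# simulate a cohort from a preset (deterministic given --seed)
cvrisk simulate --preset kora_like -n 5000 --seed 1 --out cohort.csv

# per-subject 10-year risks (default packaged coefficients)
cvrisk score --cohort cohort.csv --equation pce --out preds.csv

# train the correction factor; writes a re-loadable coefficient file
cvrisk recalibrate --cohort cohort.csv --out-coeffs recal.json

# calibration + discrimination report for existing predictions
cvrisk evaluate --cohort cohort.csv --predictions preds.csv --out report.csv

# full pipeline from a YAML run config
cvrisk run --config run.yaml --out results/
```

A minimal run config:

```yaml
name: demo
seed: 1
cohorts:
  - {label: cohort_a, preset: kora_like, true_model: pce_scaled, gamma: 1.4}
  - {label: cohort_b, preset: hnr_like}
recal_training: pooled
bootstrap: 200
cv_k: 10
```

`run` writes `summary_table.csv` (observed %, estimated %, overestimation %,
C with CI per stratum × equation), per-panel decile calibration files, a
cross-validation summary, the recalibrated coefficient JSON and a manifest
with the config hash and seed. Identical config + seed reproduce the bundle
byte for byte.

Coefficients live in versioned JSON files under `src/cvrisk/data/` and can be
overridden with `--coeffs` / the `pce_coeffs` / `esc_coeffs` config keys.

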