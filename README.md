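# traumascore

Trauma severity scoring and diagnostic-accuracy analysis for
emergency-department cohorts.

Triage scores compress bedside vitals into one number so that a
receiving clinician can predict, within seconds, which trauma patients
are likely to die without escalated care. This package implements two
such scores and the full statistical evaluation of their predictive
accuracy, for biostatisticians and emergency-medicine researchers
validating trauma triage in their own cohorts:

* **RTS** (Revised Trauma Score):
  `RTS = 0.9368·code(GCS) + 0.7326·code(SBP) + 0.2908·code(RR)`,
  where each vital is first banded to an ordinal code 0–4; range
  0–7.8408, and `RTS < 7` predicts death.
* **NTS** (New Trauma Score):
  `NTS = GCS + 0.2983·code(SBP) + 0.8709·code(SpO2)`,
  using the raw GCS and substituting oxygen saturation for respiratory
  rate; range 3–19.6768, and `NTS < 18` predicts death.

Around the scores sit the evaluation tools: 2×2 cross-tabulation of
predicted against observed mortality; sensitivity, specificity, PPV,
NPV and accuracy with Wilson 95% confidence intervals; uncorrected
Pearson chi-square association tests; combined-score analyses (pooled
and concordant-AND variants); stratified analysis across effect
modifiers (age ≤35/>35, sex, hypertension, diabetes); Buderer sample
size; and a seedable synthetic cohort generator so every pipeline stage
is testable without patient data. Band-to-code tables, weights and
cutoffs are configuration (YAML/JSON), not hard-coded.

## Worked example

Reproduce the headline accuracy analysis on the bundled exact-table
fixture cohort (366 patients engineered so that scoring and
classification land on the reference 2×2 tables):

```python
from traumascore import reference, build_report, default_config
from traumascore.synthetic import generate_matching_tables

tables, weights = default_config()
cohort = generate_matching_tables(reference.NTS_TABLE, reference.RTS_TABLE,
                                  tables, weights)
rep = build_report(cohort, tables, weights)
m = rep.nts_metrics
print(f"n = {rep.descriptives['n']}, deaths = {rep.descriptives['deaths']} "
      f"({100*rep.mortality_rate:.2f}%)")
t = rep.nts_table
print(f"NTS table: tp={t.tp} fp={t.fp} fn={t.fn} tn={t.tn}")
print(f"NTS sensitivity {m.sensitivity.percent}%  (95% CI "
      f"{m.sensitivity.ci_low:.3f}-{m.sensitivity.ci_high:.3f})")
print(f"NTS specificity {m.specificity.percent}%  accuracy {m.accuracy.percent}%")
p = rep.pooled_metrics
print(f"combined (pooled) accuracy {p.accuracy.percent}% over n = {p.n} pairs")
```

prints

```
n = 366, deaths = 17 (4.64%)
NTS table: tp=15 fp=7 fn=2 tn=342
NTS sensitivity 88.2%  (95% CI 0.657-0.967)
NTS specificity 98.0%  accuracy 97.5%
combined (pooled) accuracy 98.4% over n = 732 pairs
```

Reading: of 17 deaths the NTS flagged 15 beforehand (sensitivity
88.2%), while only 7 of 349 survivors were over-triaged (specificity
98.0%). Pooling each patient's two score classifications into one
combined table (732 prediction/outcome pairs) raises accuracy to
98.4%. The wide sensitivity CI is the price of 17 events.

## Command line

```sh
traumascore simulate cohort.csv --n 366 --seed 1   # synthetic cohort CSV
traumascore score cohort.csv scored.csv            # append rts/nts columns
traumascore evaluate cohort.csv --out report.json  # full report
traumascore reproduce                              # rebuild + check reference values
```

The cohort CSV schema is
`id,age,sex,gcs,sbp,rr,spo2,hypertension,diabetes,died` (booleans 0/1,
sex `male`/`female`). `--config` accepts a YAML/JSON file overriding
the default coding bands, weights or cutoffs (see
`src/traumascore/data/default_config.yaml`).

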