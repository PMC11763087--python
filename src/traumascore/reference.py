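"""Published reference values the default pipeline is checked against.

These are the headline 2x2 tables, accuracy metrics (1-dp percents) and
stratum chi-square statistics of the emergency-department trauma study
whose conditions the package's defaults emulate. The ``reproduce`` CLI
subcommand rebuilds each quantity from scratch through the pipeline and
compares against these values.

Two published numbers are knowingly *not* used as references because
they are inconsistent with their own printed counts: the RTS accuracy
(printed 99.1%, but 363/366 rounds to 99.2%) and the male-stratum
chi-square (printed 135.49, but the uncorrected Pearson statistic on
the printed counts is 135.44). The values below are the ones the
arithmetic supports.
"""

from __future__ import annotations

from .diagnostics import TwoByTwoTable

# Per-score 2x2 tables (prediction = score below cutoff, outcome = died).
NTS_TABLE = TwoByTwoTable(tp=15, fp=7, fn=2, tn=342)
RTS_TABLE = TwoByTwoTable(tp=15, fp=1, fn=2, tn=348)

# Pooled combined table: cell-wise sum of the two tables above (n = 732).
COMBINED_POOLED_TABLE = TwoByTwoTable(tp=30, fp=8, fn=4, tn=690)

# Accuracy metrics as percentages, rounded half-up to 1 dp.
NTS_METRICS_PCT = {
    "sensitivity": 88.2, "specificity": 98.0, "ppv": 68.2,
    "npv": 99.4, "accuracy": 97.5,
}
RTS_METRICS_PCT = {
    "sensitivity": 88.2, "specificity": 99.7, "ppv": 93.8,
    "npv": 99.4, "accuracy": 99.2,  # published as 99.1; 363/366 = 99.18%
}
COMBINED_POOLED_METRICS_PCT = {
    "sensitivity": 88.2, "specificity": 98.9, "ppv": 78.9,
    "npv": 99.4, "accuracy": 98.4,
}

# Cohort size and deaths; mortality 17/366 = 4.64%.
COHORT_N = 366
DEATHS = 17
MORTALITY_PCT = 4.64

# Stratum 2x2 tables of the combined (concordant) classification, with
# the uncorrected Pearson chi-square each implies (2 dp). The female
# stratum is omitted: its published statistic does not follow from its
# printed counts by any standard chi-square variant.
STRATUM_TABLES: dict[str, TwoByTwoTable] = {
    "age<=35": TwoByTwoTable(6, 3, 2, 260),
    "age>35": TwoByTwoTable(9, 4, 0, 82),
    "male": TwoByTwoTable(11, 7, 2, 254),
    "hypertensive": TwoByTwoTable(7, 1, 0, 13),
    "non-hypertensive": TwoByTwoTable(8, 6, 2, 329),
    "diabetic": TwoByTwoTable(5, 6, 2, 6),
    "non-diabetic": TwoByTwoTable(10, 1, 0, 336),
}
STRATUM_CHI2: dict[str, float] = {
    "age<=35": 131.91,
    "age>35": 62.71,
    "male": 135.44,  # published as 135.49; Pearson on (11,7,2,254) gives 135.44
    "hypertensive": 17.06,
    "non-hypertensive": 152.55,
    "diabetic": 0.83,
    "non-diabetic": 314.52,
}

# Design parameters of the underlying sample-size calculation:
# anticipated NTS sensitivity/specificity, trauma prevalence, absolute
# precision, confidence level.
SAMPLE_SIZE_PARAMS = {
    "sens": 0.95, "spec": 0.82, "prevalence": 0.20,
    "precision": 0.05, "conf": 0.95,
}
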