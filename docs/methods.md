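# Methods

## The scores

Both scores map bedside vital signs to a single severity number that is
then thresholded to predict in-hospital mortality.

**Revised Trauma Score (RTS).** Each of GCS, systolic blood pressure
(SBP) and respiratory rate (RR) is first mapped to an ordinal code 0
(worst) to 4 (normal) by a banded lookup, then combined as

    RTS = 0.9368·code(GCS) + 0.7326·code(SBP) + 0.2908·code(RR)

giving a range of 0 to 7.8408. A score strictly below 7 predicts death.

**New Trauma Score (NTS).** The raw GCS total (3–15) replaces the GCS
code, SpO2 replaces RR, and the SBP code gets a new weight:

    NTS = GCS + 0.2983·code(SBP) + 0.8709·code(SpO2)

giving 3 to 19.6768 under the default tables. A score strictly below 18
predicts death. Both cutoffs are strict: a patient exactly at the
cutoff is classified as a predicted survivor.

## Coding tables are configuration, not constants

The RTS bands shipped as defaults are the canonical published coding
(GCS 13–15→4 … 3→0; SBP >89→4 … 0→0; RR 10–29→4, >29→3, 6–9→2, 1–5→1,
0→0; note RR codes are not monotone in the raw value — the normal range
scores highest). The NTS bands are less standardized: the default here
reuses the RTS SBP bands for NTS-SBP and uses a five-band SpO2 coding
(≥94→4, 86–93→3, 76–85→2, 51–75→1, ≤50→0) with the same 0–4 structure.
All five tables live in `data/default_config.yaml` and can be replaced
per run; every band is a closed integer-delimited interval
`[low, high, code]`, and real-valued measurements are floored onto the
integer grid before lookup (an SBP of 89.6 has not reached the 90
boundary). GCS outside [3, 15] is rejected, never clamped: GCS is
defined on that range and silent clamping would hide data errors.

## Diagnostic accuracy

Predictions are cross-tabulated against the observed outcome into a
2×2 table (TP = predicted death, died). Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy
= (TP+TN)/n. A metric with an empty denominator (no deaths in a
stratum, say) is reported as *undefined*, never as an exception or a
NaN propagating silently.

Confidence intervals are Wilson score intervals (default 95%). With a
handful of deaths per stratum the Wald interval collapses or escapes
[0, 1]; Wilson intervals do not. Endpoints at the boundary counts
(k = 0 or k = n) are snapped to exact 0/1.

Association between the combined classification and mortality is
tested with the Pearson chi-square on 1 df **without** continuity
correction; the uncorrected statistic is what stratified reference
results in this literature follow. A table with any zero margin yields
an undefined-test marker. p-values are kept at full precision; a
separate display string floors tiny values to "<0.001".

Percent displays round half-up to 1 decimal (15/16 → 93.8%), matching
clinical reporting convention; all stored values keep full precision.

## Combining two scores

Two distinct procedures are exposed because published "combined NTS +
RTS" tables are ambiguous between them:

* **pooled** (default for reproduction): each patient contributes one
  prediction/outcome pair per score, so the combined table is the
  cell-wise sum of the two single-score tables and sums to 2n. Pooled
  sensitivity is therefore a weighted mean of the two single-score
  sensitivities.
* **concordant-AND**: combined-positive iff both scores are positive,
  combined-negative iff both are negative; discordant patients are
  excluded from the 2×2 and reported as a separate count, because no
  defensible cell assignment exists for them.

## Sample size

`buderer_sample_size` implements the Buderer formulas: with z the
normal quantile for the confidence level, d the absolute precision and
p the anticipated prevalence,

    n_sens = ceil(z²·sens(1−sens)/(d²·p)),  n_spec = ceil(z²·spec(1−spec)/(d²·(1−p)))

and the result is the larger of the two. The ceiling is applied once,
at the end; for anticipated sensitivity 0.95, specificity 0.82,
prevalence 0.20, d = 0.05 and 95% confidence this gives n = 365.
Conventions that round intermediate quantities give 366; the package
does not emulate them.

## Synthetic cohort generator

The generator emulates an adult (13–60 y) emergency-department trauma
cohort: 74.86% male, 5.74% hypertensive, 5.19% diabetic; age
31.90 ± 7.46; GCS 14.21 ± 2.45 (integer, [3, 15]), SBP 107.98 ± 14.34
mmHg, RR 21.68 ± 4.27 /min, SpO2 97.90 ± 1.07%; overall mortality near
4.64%.

Continuous vitals are truncated normals. Truncation pulls the mean of a
bounded normal away from its location parameter — severely for GCS,
whose target mean sits 0.3 SD below the ceiling — so each location
parameter is solved numerically (Brent root-finding on the
truncated-normal mean) at model construction so the *post-truncation*
mean hits the target. The scale parameter is left at the reported SD;
the realized SD is therefore somewhat smaller for heavily truncated
variables. GCS is sampled continuously, then rounded to the nearest
integer, which shifts its mean upward by ≈0.04; tests compare against
the rounding-aware expectation computed from the truncated-normal CDF.

Mortality follows a logistic link on standardized GCS, SBP and SpO2
with slopes −2.0, −0.8, −0.8 (GCS dominates, as in trauma triage
practice) and an intercept of −3.6918 calibrated once by seeded
bisection at n = 10,000 to give 4.64% overall mortality; the
calibration is reproducible via `calibrate_intercept`. Comorbidity
flags are drawn independently of vitals (no joint structure is
published to emulate).

What the generator does **not** model: injury mechanism, correlation
between vitals, time-to-death, hospital course, or the heavy left skew
real trauma-score distributions show. Tests passing on synthetic
cohorts demonstrate that the pipeline is correct and internally
consistent, not that the scores achieve any particular accuracy on
real patients — the generator's discrimination is set by its logistic
slopes, and its score operating characteristics differ from any real
registry's.

`generate_matching_tables` is the deterministic fixture builder: given
one target 2×2 table per score sharing an outcome margin, it chooses
joint classification counts with maximum overlap between the two
scores' positives (always feasible; deaths and survivors handled
separately), picks one exemplar vitals vector per joint cell by a
deterministic grid scan, and emits a cohort whose scored
classifications reproduce both tables cell for cell. Demographics in
these fixtures are filler (age 30, male, no comorbidities).

## Problem sizes and numerics

Desk-scale reproductions run on the 366-patient fixture; Monte-Carlo
checks use one cohort of 10,000 patients, where binomial noise puts
≈0.2 pp standard error on the mortality rate and ≈2 pp on a
sensitivity estimated from ~460 deaths. Wilson endpoints are checked
against an independent root-finder to 1e-10. Ties at band boundaries
cannot occur (closed integer bands partition the range); ties at the
score cutoffs are resolved by the strict-inequality rule above.

## Known limitations

* Two published reference numbers are internally inconsistent with
  their own printed counts (an accuracy of 99.1% where the counts give
  99.18%, and a male-stratum chi-square of 135.49 where the counts give
  135.44); the package reproduces the arithmetic, not the misprints,
  and `reference.py` documents both.
* The concordant-AND combined analysis discards discordant patients;
  with strongly disagreeing scores its 2×2 can be much smaller than
  the cohort.
* The generator's per-vital independence means joint tail events
  (simultaneously low GCS, SBP and SpO2) are rarer than in real
  polytrauma, which depresses score discrimination relative to real
  registries.
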