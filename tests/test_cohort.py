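"""Cohort pipeline: descriptives, single/combined/stratified accuracy, sample size."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

from traumascore.cohort import (
    PatientRecord,
    StratumSpec,
    buderer_sample_size,
    build_report,
    default_strata,
    describe,
    evaluate_combined_concordant,
    evaluate_combined_pooled,
    evaluate_score,
    score_cohort,
    stratified_analysis,
)
from traumascore.scoring import VitalSigns
from traumascore.synthetic import CohortModel, generate


def patient(i, died=False, sex="male", age=30.0, htn=False, dm=False, gcs=15,
            sbp=120, rr=16, spo2=99):
    return PatientRecord(
        id=f"p{i}", age=age, sex=sex,
        vitals=VitalSigns(gcs=gcs, sbp=sbp, rr=rr, spo2=spo2),
        hypertension=htn, diabetes=dm, died=died,
    )


@pytest.fixture(scope="module")
def mixed_cohort(tables, weights):
    """20 patients: 4 moribund deaths, 1 moribund survivor, 15 healthy."""
    cohort = (
        [patient(i, died=True, gcs=3, sbp=0, rr=0, spo2=40) for i in range(4)]
        + [patient(4, died=False, gcs=3, sbp=0, rr=0, spo2=40)]
        + [patient(5 + i, sex="female" if i % 2 else "male") for i in range(15)]
    )
    return cohort, score_cohort(cohort, tables, weights)


class TestDescribe:
    def test_mortality_and_frequencies(self, mixed_cohort):
        cohort, scored = mixed_cohort
        d = describe(cohort, scored)
        assert d["n"] == 20
        assert d["deaths"] == 4
        assert d["mortality_rate"] == pytest.approx(0.20)
        assert d["frequencies"]["male"]["count"] + d["frequencies"]["female"]["count"] == 20

    def test_single_dead_patient(self):
        d = describe([patient(0, died=True)])
        assert d["mortality_rate"] == 1.0
        assert d["quantitative"]["gcs"]["sd"] == 0.0

    def test_sample_sd_uses_n_minus_1(self):
        cohort = [patient(0, gcs=13), patient(1, gcs=15)]
        d = describe(cohort)
        assert d["quantitative"]["gcs"]["sd"] == pytest.approx(math.sqrt(2))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            describe([])


class TestEvaluate:
    def test_single_score_tables(self, mixed_cohort):
        _, scored = mixed_cohort
        for sel in ("nts", "rts"):
            t, m = evaluate_score(scored, sel)
            assert (t.tp, t.fp, t.fn, t.tn) == (4, 1, 0, 15)
            assert t.n == 20
            assert m.sensitivity.value == 1.0

    def test_all_survivor_cohort_undefined_sensitivity(self, tables, weights):
        scored = score_cohort([patient(i) for i in range(5)], tables, weights)
        t, m = evaluate_score(scored, "nts")
        assert not m.sensitivity.defined
        assert m.specificity.value == 1.0

    def test_pooled_is_cellwise_sum_and_2n(self, mixed_cohort, tables, weights):
        _, scored = mixed_cohort
        t_nts, _ = evaluate_score(scored, "nts")
        t_rts, _ = evaluate_score(scored, "rts")
        pooled, _ = evaluate_combined_pooled(scored)
        assert pooled.n == 2 * len(scored)
        assert (pooled.tp, pooled.fp, pooled.fn, pooled.tn) == (
            t_nts.tp + t_rts.tp, t_nts.fp + t_rts.fp,
            t_nts.fn + t_rts.fn, t_nts.tn + t_rts.tn,
        )

    def test_pooled_sensitivity_between_single_sensitivities(self, tables, weights):
        # engineer disagreement: deaths where only NTS is positive
        # (high RTS codes but GCS 13 keeps NTS below 18)
        cohort = (
            [patient(i, died=True, gcs=13, sbp=120, rr=16, spo2=99) for i in range(3)]
            + [patient(3, died=True, gcs=3, sbp=0, rr=0, spo2=40)]
            + [patient(4 + i) for i in range(10)]
        )
        scored = score_cohort(cohort, tables, weights)
        _, m_nts = evaluate_score(scored, "nts")
        _, m_rts = evaluate_score(scored, "rts")
        _, m_pool = evaluate_combined_pooled(scored)
        lo = min(m_nts.sensitivity.value, m_rts.sensitivity.value)
        hi = max(m_nts.sensitivity.value, m_rts.sensitivity.value)
        assert lo <= m_pool.sensitivity.value <= hi
        assert lo < hi  # the engineered cohort really does disagree

    def test_concordant_excludes_and_counts_discordant(self, tables, weights):
        cohort = (
            [patient(0, died=True, gcs=13, sbp=120, rr=16, spo2=99)]  # NTS+ only
            + [patient(1, died=True, gcs=3, sbp=0, rr=0, spo2=40)]    # both +
            + [patient(2 + i) for i in range(5)]                      # both -
        )
        scored = score_cohort(cohort, tables, weights)
        t, m, n_disc = evaluate_combined_concordant(scored)
        assert n_disc == 1
        assert t.n == 6
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 5)

    def test_concordant_equals_single_table_when_no_discordants(self, mixed_cohort):
        _, scored = mixed_cohort
        t, _, n_disc = evaluate_combined_concordant(scored)
        t_nts, _ = evaluate_score(scored, "nts")
        assert n_disc == 0
        assert t == t_nts


class TestStratified:
    def test_complementary_strata_partition_overall(self, mixed_cohort):
        _, scored = mixed_cohort
        strata = [
            StratumSpec("male", lambda r: r.sex == "male"),
            StratumSpec("female", lambda r: r.sex == "female"),
        ]
        res = stratified_analysis(scored, strata)
        overall, _, _ = evaluate_combined_concordant(scored)
        total = sum(r.n for r in res)
        assert total == len(scored)
        summed = [
            sum(getattr(r.table, c) for r in res if r.table is not None)
            for c in ("tp", "fp", "fn", "tn")
        ]
        assert summed == [overall.tp, overall.fp, overall.fn, overall.tn]

    def test_empty_stratum_reported_with_undefined_markers(self, mixed_cohort):
        _, scored = mixed_cohort
        res = stratified_analysis(scored, [StratumSpec("none", lambda r: False)])
        assert res[0].n == 0
        assert res[0].table is None and res[0].chi2 is None and res[0].metrics is None

    def test_default_strata_cover_each_axis_twice(self, mixed_cohort):
        _, scored = mixed_cohort
        res = stratified_analysis(scored, default_strata())
        assert len(res) == 8
        by_name = {r.stratum: r.n for r in res}
        assert by_name["male"] + by_name["female"] == len(scored)
        assert by_name["age<=35"] + by_name["age>35"] == len(scored)


class TestBuderer:
    def test_study_design_parameters(self):
        # anticipated sensitivity 95%, specificity 82%, prevalence 20%,
        # precision 5%, confidence 95% -> sensitivity side dominates
        n = buderer_sample_size(0.95, 0.82, 0.20, 0.05, 0.95)
        assert n == 365

    def test_max_of_both_sides(self):
        # symmetric case where the specificity side dominates
        n = buderer_sample_size(0.95, 0.50, 0.80, 0.05, 0.95)
        z = norm.ppf(0.975)
        n_spec = math.ceil(z**2 * 0.25 / (0.05**2 * 0.20))
        assert n == n_spec

    def test_monotone_in_precision(self):
        ns = [buderer_sample_size(0.9, 0.8, 0.3, d, 0.95) for d in (0.02, 0.05, 0.10)]
        assert ns[0] > ns[1] > ns[2]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            buderer_sample_size(bad, 0.8, 0.2)


class TestParameterRecovery:
    def test_estimated_accuracy_matches_generator_truth(self, tables, weights):
        """At n=10,000 the empirical sensitivity/specificity of either score
        match the generator's own conditional expectations (computed from the
        per-patient death probabilities) within Monte-Carlo tolerance."""
        model = replace(CohortModel(), n=10_000)
        cohort = generate(model, seed=11)
        scored = score_cohort(cohort, tables, weights)
        p = model.death_probability(
            np.array([r.vitals.gcs for r in cohort], dtype=float),
            np.array([r.vitals.sbp for r in cohort]),
            np.array([r.vitals.spo2 for r in cohort]),
        )
        for sel in ("nts", "rts"):
            pos = np.array([getattr(s.scores, f"{sel}_positive") for s in scored])
            true_sens = float(np.sum(p * pos) / np.sum(p))
            true_spec = float(np.sum((1 - p) * ~pos) / np.sum(1 - p))
            _, m = evaluate_score(scored, sel)
            # ~460 expected deaths -> binomial SE on sensitivity ~2.3 pp
            assert m.sensitivity.value == pytest.approx(true_sens, abs=0.08)
            assert m.specificity.value == pytest.approx(true_spec, abs=0.02)


def test_build_report_totals_conserve_cohort_size(tables, weights):
    cohort = generate(replace(CohortModel(), n=400), seed=3)
    rep = build_report(cohort, tables, weights)
    assert rep.nts_table.n == 400
    assert rep.rts_table.n == 400
    assert rep.pooled_table.n == 800
    assert rep.concordant_table.n + rep.n_discordant == 400
    d = rep.to_dict()
    assert d["combined_pooled"]["table"]["n"] == 800
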