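"""Cohort-level analysis: score every patient, then measure accuracy.

The pipeline mirrors a diagnostic-accuracy study of trauma scores in an
emergency department: compute RTS and NTS for each patient, classify
predicted mortality at the score cutoffs, cross-tabulate against the
observed outcome, and report accuracy metrics overall, for the two
scores combined, and within effect-modifier strata (age group, sex,
hypertension, diabetes).

Two readings of "combined NTS + RTS" are implemented because they are
genuinely different procedures:

* **pooled** — each patient contributes two prediction/outcome pairs,
  one per score; the combined 2x2 table is the cell-wise sum of the two
  single-score tables and sums to twice the cohort size.
* **concordant** — a patient counts as combined-positive only when both
  scores predict death and combined-negative only when both predict
  survival; patients the scores disagree on are excluded from the 2x2
  and reported as a separate discordant count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diagnostics import (
    Chi2Result,
    DiagnosticMetrics,
    TwoByTwoTable,
    confusion,
    metrics,
    pearson_chi2,
)
from .scoring import CodingTables, ScoreResult, ScoreWeights, VitalSigns, score_patient

__all__ = [
    "PatientRecord",
    "ScoredPatient",
    "StratumSpec",
    "StratumResult",
    "CohortReport",
    "score_cohort",
    "describe",
    "evaluate_score",
    "evaluate_combined_pooled",
    "evaluate_combined_concordant",
    "stratified_analysis",
    "default_strata",
    "buderer_sample_size",
    "build_report",
]

AGE_MIN, AGE_MAX = 13, 60


@dataclass(frozen=True)
class PatientRecord:
    """One emergency-department trauma patient.

    ``died`` is the outcome through hospital discharge. Age limits
    reflect the adult (13-60 y) inclusion window of the study design the
    package models; pass ``age_bounds=None`` to :func:`score_cohort` to
    lift them.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    vitals: VitalSigns
    hypertension: bool
    diabetes: bool
    died: bool

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


@dataclass(frozen=True)
class ScoredPatient:
    record: PatientRecord
    scores: ScoreResult


def score_cohort(
    cohort: Sequence[PatientRecord],
    tables: CodingTables,
    weights: ScoreWeights = ScoreWeights(),
) -> list[ScoredPatient]:
    """Score every patient; coding errors propagate with the patient id."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    out = []
    for rec in cohort:
        try:
            out.append(ScoredPatient(rec, score_patient(rec.vitals, tables, weights)))
        except Exception as exc:
            raise type(exc)(f"patient {rec.id}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Descriptive statistics


def describe(cohort: Sequence[PatientRecord], scored: Sequence[ScoredPatient] | None = None) -> dict:
    """Table-1/Table-2 style descriptives.

    Mean, sample SD (n-1), min and max per quantitative variable;
    frequency and percentage for sex and comorbidities; mortality rate.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        {
            "age": [r.age for r in cohort],
            "gcs": [r.vitals.gcs for r in cohort],
            "sbp": [r.vitals.sbp for r in cohort],
            "rr": [r.vitals.rr for r in cohort],
            "spo2": [r.vitals.spo2 for r in cohort],
        }
    )
    if scored is not None:
        df["rts"] = [s.scores.rts for s in scored]
        df["nts"] = [s.scores.nts for s in scored]
    quantitative = {
        col: {
            "mean": float(df[col].mean()),
            "sd": float(df[col].std(ddof=1)) if len(df) > 1 else 0.0,
            "min": float(df[col].min()),
            "max": float(df[col].max()),
        }
        for col in df.columns
    }
    n = len(cohort)
    deaths = sum(r.died for r in cohort)

    def freq(k: int) -> dict:
        return {"count": k, "percent": 100.0 * k / n}

    return {
        "n": n,
        "quantitative": quantitative,
        "frequencies": {
            "male": freq(sum(r.sex == "male" for r in cohort)),
            "female": freq(sum(r.sex == "female" for r in cohort)),
            "hypertension": freq(sum(r.hypertension for r in cohort)),
            "diabetes": freq(sum(r.diabetes for r in cohort)),
        },
        "deaths": deaths,
        "mortality_rate": deaths / n,
    }


# ---------------------------------------------------------------------------
# Accuracy evaluation


def _pairs(
    scored: Sequence[ScoredPatient], selector: str
) -> tuple[list[bool], list[bool]]:
    if selector not in ("nts", "rts"):
        raise ValueError(f"score_selector must be 'nts' or 'rts', got {selector!r}")
    attr = f"{selector}_positive"
    preds = [getattr(s.scores, attr) for s in scored]
    outcomes = [s.record.died for s in scored]
    return preds, outcomes


def evaluate_score(
    scored: Sequence[ScoredPatient], score_selector: str, conf: float = 0.95
) -> tuple[TwoByTwoTable, DiagnosticMetrics]:
    """2x2 table and metrics for one score ('nts' or 'rts')."""
    preds, outcomes = _pairs(scored, score_selector)
    t = confusion(preds, outcomes)
    return t, metrics(t, conf)


def evaluate_combined_pooled(
    scored: Sequence[ScoredPatient], conf: float = 0.95
) -> tuple[TwoByTwoTable, DiagnosticMetrics]:
    """Pooled combined table: cell-wise sum of the NTS and RTS tables."""
    t_nts, _ = evaluate_score(scored, "nts", conf)
    t_rts, _ = evaluate_score(scored, "rts", conf)
    t = t_nts + t_rts
    return t, metrics(t, conf)


def evaluate_combined_concordant(
    scored: Sequence[ScoredPatient], conf: float = 0.95
) -> tuple[TwoByTwoTable, DiagnosticMetrics, int]:
    """Concordant-AND combined table; discordant patients counted separately.

    Returns ``(table, metrics, n_discordant)``.
    """
    concordant = [
        s for s in scored if s.scores.nts_positive == s.scores.rts_positive
    ]
    n_disc = len(scored) - len(concordant)
    if not concordant:
        raise ValueError("all patients are discordant; concordant table is empty")
    preds = [s.scores.nts_positive for s in concordant]
    outcomes = [s.record.died for s in concordant]
    t = confusion(preds, outcomes)
    return t, metrics(t, conf), n_disc


# ---------------------------------------------------------------------------
# Stratified analysis


@dataclass(frozen=True)
class StratumSpec:
    """A named subgroup predicate over patient records."""

    name: str
    predicate: Callable[[PatientRecord], bool]


def default_strata(age_split: float = 35.0) -> list[StratumSpec]:
    """The effect-modifier strata: age <=35 / >35, sex, hypertension, diabetes."""
    return [
        StratumSpec(f"age<={age_split:g}", lambda r, a=age_split: r.age <= a),
        StratumSpec(f"age>{age_split:g}", lambda r, a=age_split: r.age > a),
        StratumSpec("male", lambda r: r.sex == "male"),
        StratumSpec("female", lambda r: r.sex == "female"),
        StratumSpec("hypertensive", lambda r: r.hypertension),
        StratumSpec("non-hypertensive", lambda r: not r.hypertension),
        StratumSpec("diabetic", lambda r: r.diabetes),
        StratumSpec("non-diabetic", lambda r: not r.diabetes),
    ]


@dataclass(frozen=True)
class StratumResult:
    stratum: str
    n: int
    table: TwoByTwoTable | None
    chi2: Chi2Result | None
    metrics: DiagnosticMetrics | None
    n_discordant: int = 0


def stratified_analysis(
    scored: Sequence[ScoredPatient],
    strata: Sequence[StratumSpec],
    evaluator: Callable[[Sequence[ScoredPatient]], tuple] = evaluate_combined_concordant,
    conf: float = 0.95,
) -> list[StratumResult]:
    """Per-stratum 2x2 table, uncorrected chi-square and metrics.

    ``evaluator`` decides how the combined prediction is formed; the
    default is the concordant-AND reading. Empty strata are reported
    with undefined markers, never dropped.
    """
    results = []
    for spec in strata:
        members = [s for s in scored if spec.predicate(s.record)]
        if not members:
            results.append(StratumResult(spec.name, 0, None, None, None))
            continue
        out = evaluator(members, conf)
        t, m = out[0], out[1]
        n_disc = out[2] if len(out) > 2 else 0
        results.append(
            StratumResult(spec.name, len(members), t, pearson_chi2(t), m, n_disc)
        )
    return results


# ---------------------------------------------------------------------------
# Sample size


def buderer_sample_size(
    sens: float,
    spec: float,
    prevalence: float,
    precision: float = 0.05,
    conf: float = 0.95,
) -> int:
    """Buderer sample size for a diagnostic-accuracy study.

    n_sens = ceil(z^2 * sens(1-sens) / (d^2 * prev)) guarantees the
    sensitivity estimate's half-width d at the anticipated prevalence;
    n_spec is the analogue on the specificity side with 1 - prev.
    Returns max(n_sens, n_spec).
    """
    for name, val in [
        ("sens", sens), ("spec", spec), ("prevalence", prevalence),
        ("precision", precision), ("conf", conf),
    ]:
        if not 0 < val < 1:
            raise ValueError(f"{name} must be in (0, 1), got {val}")
    z = sps.norm.ppf(1 - (1 - conf) / 2)
    n_sens = math.ceil(z**2 * sens * (1 - sens) / (precision**2 * prevalence))
    n_spec = math.ceil(z**2 * spec * (1 - spec) / (precision**2 * (1 - prevalence)))
    return max(n_sens, n_spec)


# ---------------------------------------------------------------------------
# Full report


@dataclass
class CohortReport:
    """Everything the analysis produces for one cohort.

    Shapes follow the study's printed tables: per-variable descriptives
    and frequencies, per-score accuracy, combined accuracy (pooled and
    concordant variants), and per-stratum chi-square association plus
    accuracy of the combined prediction.
    """

    descriptives: dict
    nts_table: TwoByTwoTable
    nts_metrics: DiagnosticMetrics
    rts_table: TwoByTwoTable
    rts_metrics: DiagnosticMetrics
    pooled_table: TwoByTwoTable
    pooled_metrics: DiagnosticMetrics
    concordant_table: TwoByTwoTable
    concordant_metrics: DiagnosticMetrics
    n_discordant: int
    strata: list[StratumResult]

    @property
    def mortality_rate(self) -> float:
        return self.descriptives["mortality_rate"]

    def to_dict(self) -> dict:
        def table_dict(t: TwoByTwoTable) -> dict:
            return {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "n": t.n}

        return {
            "descriptives": self.descriptives,
            "nts": {"table": table_dict(self.nts_table), **self.nts_metrics.to_dict()},
            "rts": {"table": table_dict(self.rts_table), **self.rts_metrics.to_dict()},
            "combined_pooled": {
                "table": table_dict(self.pooled_table),
                **self.pooled_metrics.to_dict(),
            },
            "combined_concordant": {
                "table": table_dict(self.concordant_table),
                "n_discordant": self.n_discordant,
                **self.concordant_metrics.to_dict(),
            },
            "strata": [
                {
                    "stratum": s.stratum,
                    "n": s.n,
                    "table": None if s.table is None else table_dict(s.table),
                    "chi2": None if s.chi2 is None else s.chi2.statistic,
                    "p_value": None if s.chi2 is None else s.chi2.p_value,
                    "p_display": None if s.chi2 is None else s.chi2.p_display,
                    "n_discordant": s.n_discordant,
                    "metrics": None if s.metrics is None else s.metrics.to_dict(),
                }
                for s in self.strata
            ],
        }


def build_report(
    cohort: Sequence[PatientRecord],
    tables: CodingTables,
    weights: ScoreWeights = ScoreWeights(),
    strata: Sequence[StratumSpec] | None = None,
    conf: float = 0.95,
) -> CohortReport:
    """Run the full pipeline on a cohort and assemble the report."""
    scored = score_cohort(cohort, tables, weights)
    nts_t, nts_m = evaluate_score(scored, "nts", conf)
    rts_t, rts_m = evaluate_score(scored, "rts", conf)
    pooled_t, pooled_m = evaluate_combined_pooled(scored, conf)
    conc_t, conc_m, n_disc = evaluate_combined_concordant(scored, conf)
    strata_results = stratified_analysis(
        scored, default_strata() if strata is None else strata, conf=conf
    )
    return CohortReport(
        descriptives=describe(cohort, scored),
        nts_table=nts_t,
        nts_metrics=nts_m,
        rts_table=rts_t,
        rts_metrics=rts_m,
        pooled_table=pooled_t,
        pooled_metrics=pooled_m,
        concordant_table=conc_t,
        concordant_metrics=conc_m,
        n_discordant=n_disc,
        strata=strata_results,
    )
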