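"""Diagnostic-accuracy metrics and association tests for 2x2 tables.

The central object is :class:`TwoByTwoTable`, the cross-classification
of a binary prediction (predicted death) against the observed outcome
(died). From it we derive sensitivity, specificity, predictive values
and accuracy with Wilson score confidence intervals, and the Pearson
chi-square test of association *without* continuity correction.

A metric whose denominator is empty (e.g. sensitivity in a cohort with
no deaths) is reported as undefined (``value is None``) rather than
raising, so stratified analyses degrade gracefully in small strata.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TwoByTwoTable",
    "Estimate",
    "DiagnosticMetrics",
    "Chi2Result",
    "confusion",
    "metrics",
    "wilson_ci",
    "pearson_chi2",
    "round_percent",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """TP/FP/FN/TN counts (prediction = predicted death, outcome = died)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def outcome_pos(self) -> int:
        """Number who died."""
        return self.tp + self.fn

    @property
    def outcome_neg(self) -> int:
        """Number who survived."""
        return self.fp + self.tn

    @property
    def pred_pos(self) -> int:
        """Number predicted to die."""
        return self.tp + self.fp

    @property
    def pred_neg(self) -> int:
        return self.fn + self.tn

    def __add__(self, other: "TwoByTwoTable") -> "TwoByTwoTable":
        """Cell-wise pooling of two tables."""
        return TwoByTwoTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def confusion(
    predictions: Sequence[bool], outcomes: Sequence[bool]
) -> TwoByTwoTable:
    """Build the 2x2 table from paired prediction/outcome sequences."""
    if len(predictions) != len(outcomes):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions, {len(outcomes)} outcomes"
        )
    if len(predictions) == 0:
        raise ValueError("empty input: need at least one prediction/outcome pair")
    p = np.asarray(predictions, dtype=bool)
    o = np.asarray(outcomes, dtype=bool)
    return TwoByTwoTable(
        tp=int(np.sum(p & o)),
        fp=int(np.sum(p & ~o)),
        fn=int(np.sum(~p & o)),
        tn=int(np.sum(~p & ~o)),
    )


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    Preferred over the Wald interval because the cell counts here are
    small (a handful of deaths); Wald intervals collapse or escape
    [0, 1] in that regime while Wilson intervals do not.
    """
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    # the Wilson endpoints are exactly 0/1 at the boundary counts; snap
    # away the last-ulp float noise so the [0, 1] invariant is exact
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


@dataclass(frozen=True)
class Estimate:
    """A proportion with its numerator, denominator and Wilson CI.

    ``value`` is ``None`` when the denominator is zero (undefined
    metric), in which case the CI endpoints are ``None`` too.
    """

    numerator: int
    denominator: int
    value: float | None
    ci_low: float | None
    ci_high: float | None

    @classmethod
    def from_counts(cls, k: int, n: int, conf: float = 0.95) -> "Estimate":
        if n == 0:
            return cls(k, 0, None, None, None)
        lo, hi = wilson_ci(k, n, conf)
        return cls(k, n, k / n, lo, hi)

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def percent(self) -> float | None:
        """Point estimate as a percentage rounded half-up to 1 dp."""
        return None if self.value is None else round_percent(self.value)


def round_percent(proportion: float, digits: int = 1) -> float:
    """Proportion -> percent, rounded half-up to ``digits`` decimals.

    Half-up (0.975 -> 97.5, 0.9375 -> 93.8) matches how clinical papers
    typically print accuracy tables; Python's builtin ``round`` is
    half-even and would disagree on exact halves.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(proportion * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy for one table."""

    table: TwoByTwoTable
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate

    @property
    def n(self) -> int:
        return self.table.n

    def to_dict(self, percent: bool = False) -> dict:
        """Flat dict for a report row (full precision, or 1-dp percents)."""
        t = self.table
        out: dict = {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "n": t.n}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            est: Estimate = getattr(self, name)
            out[name] = est.percent if percent else est.value
            if not percent:
                out[f"{name}_ci_low"] = est.ci_low
                out[f"{name}_ci_high"] = est.ci_high
        return out


def metrics(t: TwoByTwoTable, conf: float = 0.95) -> DiagnosticMetrics:
    """All five accuracy metrics with Wilson CIs for a 2x2 table.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    ppv = tp/(tp+fp), npv = tn/(tn+fn), accuracy = (tp+tn)/n.
    """
    if t.n == 0:
        raise ValueError("cannot compute metrics on an empty table")
    return DiagnosticMetrics(
        table=t,
        sensitivity=Estimate.from_counts(t.tp, t.outcome_pos, conf),
        specificity=Estimate.from_counts(t.tn, t.outcome_neg, conf),
        ppv=Estimate.from_counts(t.tp, t.pred_pos, conf),
        npv=Estimate.from_counts(t.tn, t.pred_neg, conf),
        accuracy=Estimate.from_counts(t.tp + t.tn, t.n, conf),
    )


@dataclass(frozen=True)
class Chi2Result:
    """Uncorrected Pearson chi-square test on a 2x2 table.

    ``statistic`` and ``p_value`` are ``None`` when a marginal total is
    zero (the test is undefined). ``p_display`` floors tiny p-values to
    the conventional "<0.001" string while ``p_value`` stays exact.
    """

    statistic: float | None
    df: int
    p_value: float | None

    @property
    def defined(self) -> bool:
        return self.statistic is not None

    @property
    def significant(self) -> bool | None:
        """Significance at the 0.05 level; None if undefined."""
        return None if self.p_value is None else self.p_value <= 0.05

    @property
    def p_display(self) -> str:
        if self.p_value is None:
            return "NA"
        if self.p_value < 0.001:
            return "<0.001"
        return f"{self.p_value:.3f}"


def pearson_chi2(t: TwoByTwoTable) -> Chi2Result:
    """Pearson chi-square test of association, df = 1, no Yates correction.

    Equivalent closed form:
    n * (tp*tn - fp*fn)^2 / [(tp+fp)(fn+tn)(tp+fn)(fp+tn)].
    """
    if t.n == 0:
        raise ValueError("cannot test an empty table")
    if 0 in (t.pred_pos, t.pred_neg, t.outcome_pos, t.outcome_neg):
        return Chi2Result(statistic=None, df=1, p_value=None)
    res = stats.chi2_contingency(t.as_array(), correction=False)
    return Chi2Result(statistic=float(res.statistic), df=1, p_value=float(res.pvalue))
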