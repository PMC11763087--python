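"""Trauma severity scores from emergency-department vital signs.

Two scores are implemented:

* **RTS** (Revised Trauma Score): a weighted sum of ordinal 0-4 codes
  assigned to Glasgow Coma Scale (GCS), systolic blood pressure (SBP)
  and respiratory rate (RR)::

      RTS = 0.9368 * code(GCS) + 0.7326 * code(SBP) + 0.2908 * code(RR)

  Range 0 to 7.8408 under the default coding tables; a score below 7
  predicts death.

* **NTS** (New Trauma Score): the *raw* GCS total plus weighted 0-4
  codes for SBP and peripheral oxygen saturation (SpO2)::

      NTS = GCS + 0.2983 * code(SBP) + 0.8709 * code(SpO2)

  Range 3 to 19.6768 under the default coding tables; a score below 18
  predicts death.

The band-to-code lookup tables are configuration data
(:class:`CodingTables`), not constants: different registries publish
slightly different bands, so the defaults shipped in
``data/default_config.yaml`` can be overridden per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "CodingError",
    "VitalSigns",
    "Band",
    "BandTable",
    "CodingTables",
    "ScoreWeights",
    "ScoreResult",
    "code_value",
    "rts",
    "nts",
    "classify",
    "score_patient",
]


class CodingError(ValueError):
    """A physiologic value fell outside every band of its coding table."""


@dataclass(frozen=True)
class VitalSigns:
    """One patient's scored vital signs.

    Parameters
    ----------
    gcs : int
        Glasgow Coma Scale total, integer in [3, 15]. Values outside the
        defined range are rejected, never clamped: a GCS of 16 is a data
        error, not a very alert patient.
    sbp : float
        Systolic blood pressure in mmHg, >= 0.
    rr : float
        Respiratory rate in breaths/min, >= 0.
    spo2 : float
        Peripheral oxygen saturation in percent, in [0, 100].
    """

    gcs: int
    sbp: float
    rr: float
    spo2: float

    def __post_init__(self) -> None:
        if not (isinstance(self.gcs, int) or float(self.gcs).is_integer()):
            raise ValueError(f"gcs must be an integer, got {self.gcs!r}")
        g = int(self.gcs)
        if not 3 <= g <= 15:
            raise ValueError(f"gcs must be in [3, 15], got {self.gcs}")
        object.__setattr__(self, "gcs", g)
        if self.sbp < 0:
            raise ValueError(f"sbp must be >= 0, got {self.sbp}")
        if self.rr < 0:
            raise ValueError(f"rr must be >= 0, got {self.rr}")
        if not 0 <= self.spo2 <= 100:
            raise ValueError(f"spo2 must be in [0, 100], got {self.spo2}")


@dataclass(frozen=True)
class Band:
    """Closed integer-delimited interval [low, high] mapped to a code.

    ``high`` may be ``None`` for an unbounded upper band (e.g. SBP > 89).
    """

    low: int
    high: int | None
    code: int

    def __post_init__(self) -> None:
        if self.high is not None and self.high < self.low:
            raise ValueError(f"band upper bound {self.high} below lower {self.low}")
        if not 0 <= self.code <= 4:
            raise ValueError(f"band code must be in [0, 4], got {self.code}")

    def contains(self, value: int) -> bool:
        return value >= self.low and (self.high is None or value <= self.high)


class BandTable:
    """Ordered, disjoint, covering set of bands for one vital sign.

    Real-valued inputs are floored to the integer grid before lookup, so
    an SBP of 89.6 mmHg falls in the 76-89 band: the bands are delimited
    on integers and a measurement strictly below the next boundary has
    not reached it.
    """

    def __init__(self, name: str, bands: Sequence[Band], domain_min: int = 0):
        self.name = name
        self.bands = sorted(bands, key=lambda b: b.low)
        self.domain_min = domain_min
        self._validate()

    def _validate(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.name}: empty band table")
        if self.bands[0].low > self.domain_min:
            raise ValueError(
                f"{self.name}: bands do not cover the domain minimum {self.domain_min}"
            )
        for a, b in zip(self.bands, self.bands[1:]):
            if a.high is None:
                raise ValueError(f"{self.name}: unbounded band is not last")
            if b.low != a.high + 1:
                raise ValueError(
                    f"{self.name}: gap or overlap between [{a.low},{a.high}] "
                    f"and [{b.low},{b.high}]"
                )

    @property
    def max_value(self) -> int | None:
        """Upper edge of the covered domain, or None if unbounded."""
        return self.bands[-1].high

    def code(self, value: float) -> int:
        v = math.floor(value)
        for band in self.bands:
            if band.contains(v):
                return band.code
        raise CodingError(
            f"{self.name}: value {value} outside all bands "
            f"(covered: {self.domain_min}..{self.max_value})"
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        spans = ", ".join(
            f"[{b.low},{'inf' if b.high is None else b.high}]->{b.code}"
            for b in self.bands
        )
        return f"BandTable({self.name}: {spans})"


@dataclass
class CodingTables:
    """The five band-to-code lookup tables the two scores need.

    RTS codes GCS, SBP and RR; NTS codes SBP (possibly on different
    bands) and SpO2. Construct via :func:`traumascore.config.load_config`
    or :func:`traumascore.config.default_config` rather than by hand.
    """

    gcs: BandTable
    sbp_rts: BandTable
    rr: BandTable
    sbp_nts: BandTable
    spo2: BandTable


@dataclass(frozen=True)
class ScoreWeights:
    """Score coefficients and decision cutoffs.

    Defaults are the published RTS regression weights and the NTS
    coefficients; cutoffs are strict (score < cutoff predicts death).
    """

    rts_gcs_w: float = 0.9368
    rts_sbp_w: float = 0.7326
    rts_rr_w: float = 0.2908
    nts_sbp_w: float = 0.2983
    nts_spo2_w: float = 0.8709
    rts_cutoff: float = 7.0
    nts_cutoff: float = 18.0

    def __post_init__(self) -> None:
        for name in (
            "rts_gcs_w", "rts_sbp_w", "rts_rr_w",
            "nts_sbp_w", "nts_spo2_w", "rts_cutoff", "nts_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rts_max(self) -> float:
        return 4 * (self.rts_gcs_w + self.rts_sbp_w + self.rts_rr_w)

    @property
    def nts_max(self) -> float:
        return 15 + 4 * (self.nts_sbp_w + self.nts_spo2_w)


@dataclass(frozen=True)
class ScoreResult:
    """Both scores and their cutoff classifications for one patient."""

    rts: float
    nts: float
    rts_positive: bool  # predicted death: rts < rts_cutoff
    nts_positive: bool  # predicted death: nts < nts_cutoff


def code_value(value: float, table: BandTable) -> int:
    """Look up the ordinal 0-4 code of ``value`` in ``table``.

    Raises :class:`CodingError` naming the variable if the value lies
    outside every band.
    """
    return table.code(value)


def rts(v: VitalSigns, tables: CodingTables, w: ScoreWeights = ScoreWeights()) -> float:
    """Revised Trauma Score: weighted sum of GCS, SBP and RR codes."""
    return (
        w.rts_gcs_w * tables.gcs.code(v.gcs)
        + w.rts_sbp_w * tables.sbp_rts.code(v.sbp)
        + w.rts_rr_w * tables.rr.code(v.rr)
    )


def nts(v: VitalSigns, tables: CodingTables, w: ScoreWeights = ScoreWeights()) -> float:
    """New Trauma Score: raw GCS plus weighted SBP and SpO2 codes."""
    return (
        v.gcs
        + w.nts_sbp_w * tables.sbp_nts.code(v.sbp)
        + w.nts_spo2_w * tables.spo2.code(v.spo2)
    )


def classify(score: float, cutoff: float) -> bool:
    """True (predicted death) iff ``score`` is strictly below ``cutoff``.

    The comparison is strict: a patient sitting exactly at the cutoff
    belongs to the predicted-survivor class.
    """
    return score < cutoff


def score_patient(
    v: VitalSigns, tables: CodingTables, w: ScoreWeights = ScoreWeights()
) -> ScoreResult:
    """Compute both scores and both cutoff classifications for one patient."""
    r = rts(v, tables, w)
    n = nts(v, tables, w)
    return ScoreResult(
        rts=r,
        nts=n,
        rts_positive=classify(r, w.rts_cutoff),
        nts_positive=classify(n, w.nts_cutoff),
    )
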