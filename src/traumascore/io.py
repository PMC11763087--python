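"""Cohort CSV input/output.

The cohort schema is a flat CSV with header
``id,age,sex,gcs,sbp,rr,spo2,hypertension,diabetes,died`` — booleans as
0/1, sex as ``male``/``female``. Reading validates every row and either
hard-fails on the first bad row (default) or skips bad rows while
collecting their errors with row context.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import PatientRecord
from .scoring import VitalSigns

__all__ = ["COHORT_COLUMNS", "RowError", "read_cohort", "write_cohort"]

COHORT_COLUMNS = [
    "id", "age", "sex", "gcs", "sbp", "rr", "spo2",
    "hypertension", "diabetes", "died",
]


@dataclass(frozen=True)
class RowError:
    """A validation failure for one CSV row (1-based data row number)."""

    row: int
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.message}"


def _parse_bool(value, field: str) -> bool:
    s = str(value).strip().lower()
    if s in ("0", "false"):
        return False
    if s in ("1", "true"):
        return True
    raise ValueError(f"{field} must be 0/1, got {value!r}")


def _parse_row(row: pd.Series) -> PatientRecord:
    sex = str(row["sex"]).strip().lower()
    vitals = VitalSigns(
        gcs=int(float(row["gcs"])),
        sbp=float(row["sbp"]),
        rr=float(row["rr"]),
        spo2=float(row["spo2"]),
    )
    return PatientRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=sex,
        vitals=vitals,
        hypertension=_parse_bool(row["hypertension"], "hypertension"),
        diabetes=_parse_bool(row["diabetes"], "diabetes"),
        died=_parse_bool(row["died"], "died"),
    )


def read_cohort(
    path: str | Path, on_error: str = "raise"
) -> tuple[list[PatientRecord], list[RowError]]:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path : str or Path
    on_error : {"raise", "skip"}
        "raise": the first invalid row aborts with an error naming the
        row and field. "skip": invalid rows are dropped and returned as
        :class:`RowError` objects alongside the valid records.

    Returns
    -------
    (records, errors)
        ``errors`` is always empty when ``on_error="raise"``.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[PatientRecord] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            err = RowError(row=int(i) + 1, message=str(exc))
            if on_error == "raise":
                raise ValueError(f"{path}: {err}") from exc
            errors.append(err)
    return records, errors


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records in the standard cohort CSV schema (booleans as 0/1)."""
    rows = [
        {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "gcs": r.vitals.gcs,
            "sbp": r.vitals.sbp,
            "rr": r.vitals.rr,
            "spo2": r.vitals.spo2,
            "hypertension": int(r.hypertension),
            "diabetes": int(r.diabetes),
            "died": int(r.died),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)
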