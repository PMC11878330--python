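"""CSV readers and writers for the three case/aggregate data layouts.

Formats
-------
ED attendances (one row per visit)::

    attendance_id, ed_id, admission_datetime (ISO-8601), age_group_lower,
    sex, triage, chief_complaint, diagnoses, disposition

``diagnoses`` is a semicolon-separated list of ``CODE:CERTAINTY`` pairs
(certainty as qualifier letter G/V/A/Z or long name; empty = no qualifier).

Inpatient records::

    attendance_id, discharge_diagnoses

``discharge_diagnoses`` is a semicolon-separated code list; a ``*`` suffix
marks the main diagnosis.

Hospital diagnosis statistics::

    year, icd_group, age_group, sex, count

Parsing is lenient where surveillance practice demands it: unknown enum
labels (sex, triage, disposition, certainty) are mapped to *missing* and
counted in a logged warning, whereas structural problems (missing columns,
duplicate attendance ids, malformed ICD codes) are hard errors.
"""

from __future__ import annotations

import logging
from datetime import datetime
from pathlib import Path
from typing import Sequence

import pandas as pd

from .codes import normalize_icd
from .records import (
    CERTAINTY_ALIASES,
    Certainty,
    DiagnosisEntry,
    Disposition,
    EDAttendance,
    HospitalStatTable,
    InpatientRecord,
    Sex,
)

logger = logging.getLogger(__name__)

ED_COLUMNS = [
    "attendance_id",
    "ed_id",
    "admission_datetime",
    "age_group_lower",
    "sex",
    "triage",
    "chief_complaint",
    "diagnoses",
    "disposition",
]
INPATIENT_COLUMNS = ["attendance_id", "discharge_diagnoses"]
HOSPITAL_STAT_COLUMNS = ["year", "icd_group", "age_group", "sex", "count"]

_SEX_ALIASES = {
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "w": Sex.FEMALE,
    "male": Sex.MALE,
    "m": Sex.MALE,
    "other": Sex.OTHER,
    "": Sex.OTHER,
}
_DISPOSITION_ALIASES = {d.value: d for d in Disposition} | {"": Disposition.MISSING}


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing required column(s): {missing}")


def _check_unique_ids(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(
            f"duplicate attendance_id in {what} file: {sorted(set(dup))[:5]}"
        )


def _parse_diagnoses(cell: str) -> list:
    entries = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        code_str, _, cert_str = part.partition(":")
        cert = CERTAINTY_ALIASES.get(cert_str.strip().lower())
        if cert is None:
            cert = Certainty.MISSING
            _parse_diagnoses.unknown += 1  # type: ignore[attr-defined]
        entries.append(DiagnosisEntry(code=normalize_icd(code_str), certainty=cert))
    return entries


def read_ed_table(path: str | Path) -> list[EDAttendance]:
    """Read an ED attendance CSV into typed records.

    Unknown sex/triage/disposition/certainty labels become *missing* and are
    counted in one summary warning; missing columns or duplicate attendance
    ids raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ED_COLUMNS, "ED attendance")
    _check_unique_ids(df["attendance_id"], "ED attendance")

    unknown = 0
    _parse_diagnoses.unknown = 0  # type: ignore[attr-defined]
    records: list[EDAttendance] = []
    for row in df.itertuples(index=False):
        sex = _SEX_ALIASES.get(row.sex.strip().lower())
        if sex is None:
            sex, unknown = Sex.OTHER, unknown + 1
        triage: int | None
        t = row.triage.strip()
        if t in ("1", "2", "3", "4", "5"):
            triage = int(t)
        else:
            triage = None
            if t not in ("", "missing"):
                unknown += 1
        disposition = _DISPOSITION_ALIASES.get(row.disposition.strip().lower())
        if disposition is None:
            disposition, unknown = Disposition.MISSING, unknown + 1
        complaint = row.chief_complaint.strip() or None
        records.append(
            EDAttendance(
                attendance_id=row.attendance_id,
                ed_id=row.ed_id,
                admission_date=datetime.fromisoformat(row.admission_datetime).date(),
                age_group_lower=int(row.age_group_lower),
                sex=sex,
                triage=triage,
                chief_complaint=complaint,
                diagnoses=_parse_diagnoses(row.diagnoses),
                disposition=disposition,
            )
        )
    unknown += _parse_diagnoses.unknown  # type: ignore[attr-defined]
    if unknown:
        logger.warning(
            "read_ed_table(%s): %d unknown field value(s) mapped to missing",
            path,
            unknown,
        )
    return records


def write_ed_table(records: Sequence[EDAttendance], path: str | Path) -> None:
    """Write ED attendances in the CSV layout read by :func:`read_ed_table`."""
    rows = []
    for a in records:
        dx = ";".join(
            f"{d.code.raw}:{'' if d.certainty is Certainty.MISSING else d.certainty.value}"
            for d in a.diagnoses
        )
        rows.append(
            {
                "attendance_id": a.attendance_id,
                "ed_id": a.ed_id,
                "admission_datetime": a.admission_date.isoformat(),
                "age_group_lower": a.age_group_lower,
                "sex": a.sex.value,
                "triage": "" if a.triage is None else a.triage,
                "chief_complaint": a.chief_complaint or "",
                "diagnoses": dx,
                "disposition": a.disposition.value,
            }
        )
    pd.DataFrame(rows, columns=ED_COLUMNS).to_csv(path, index=False)


def read_inpatient_table(path: str | Path) -> list[InpatientRecord]:
    """Read inpatient discharge records; ``*`` marks the main diagnosis."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, INPATIENT_COLUMNS, "inpatient")
    _check_unique_ids(df["attendance_id"], "inpatient")
    records = []
    for row in df.itertuples(index=False):
        dx = []
        for part in str(row.discharge_diagnoses).split(";"):
            part = part.strip()
            if not part:
                continue
            is_main = part.endswith("*")
            dx.append((normalize_icd(part.rstrip("*")), is_main))
        records.append(InpatientRecord(attendance_id=row.attendance_id, discharge_diagnoses=dx))
    return records


def write_inpatient_table(records: Sequence[InpatientRecord], path: str | Path) -> None:
    rows = [
        {
            "attendance_id": r.attendance_id,
            "discharge_diagnoses": ";".join(
                c.raw + ("*" if main else "") for c, main in r.discharge_diagnoses
            ),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=INPATIENT_COLUMNS).to_csv(path, index=False)


def read_hospital_stats(path: str | Path) -> HospitalStatTable:
    """Read the yearly aggregated hospital diagnosis statistics table."""
    df = pd.read_csv(path, dtype={"year": int, "count": int})
    _require_columns(df, HOSPITAL_STAT_COLUMNS, "hospital statistics")
    df = df.rename(columns={"age_group": "age_band"})
    return HospitalStatTable(df)


def write_hospital_stats(table: HospitalStatTable, path: str | Path) -> None:
    out = table.df.rename(columns={"age_band": "age_group"})
    out.to_csv(path, index=False)
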