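"""Domain records for case-based emergency-department surveillance data.

The layout follows the German NoKeDa ("Notaufnahme-Kerndatensatz") core data
model for ED surveillance transfers: one row per ED attendance with coarse
demographics (5-year age band, sex), administrative fields (facility, admission
date, triage urgency, disposition), a CEDIS-PCL chief complaint and zero or
more ICD-10-GM diagnoses with certainty qualifiers.  Inpatient billing records
(discharge diagnoses) link to attendances through a shared opaque identifier.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .codes import ICDCode

__all__ = [
    "Sex",
    "Certainty",
    "Disposition",
    "DiagnosisEntry",
    "EDAttendance",
    "InpatientRecord",
    "LinkedCase",
    "HospitalStatTable",
    "link_cases",
    "ANALYSIS_AGE_BANDS",
]

#: 20-year analysis bands used for stratified external comparison.
ANALYSIS_AGE_BANDS = ("0-19", "20-39", "40-59", "60-79", "80+")


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"  # other or missing


class Certainty(str, enum.Enum):
    """ICD-10-GM diagnosis certainty qualifier.

    German coding appends a qualifier letter to outpatient/ED diagnoses:
    G = confirmed ("gesichert"), V = suspected ("Verdacht auf"),
    A = excluded ("Ausschluss"), Z = status post ("Zustand nach").
    Diagnoses documented without a qualifier are ``MISSING``.
    """

    CONFIRMED = "confirmed"
    SUSPECTED = "suspected"
    EXCLUDED = "excluded"
    STATUS_POST = "status_post"
    MISSING = "missing"


#: accepted spellings in input files (qualifier letters and long names)
CERTAINTY_ALIASES = {
    "g": Certainty.CONFIRMED,
    "confirmed": Certainty.CONFIRMED,
    "v": Certainty.SUSPECTED,
    "suspected": Certainty.SUSPECTED,
    "a": Certainty.EXCLUDED,
    "excluded": Certainty.EXCLUDED,
    "z": Certainty.STATUS_POST,
    "status_post": Certainty.STATUS_POST,
    "": Certainty.MISSING,
    "missing": Certainty.MISSING,
}


class Disposition(str, enum.Enum):
    INPATIENT_ADMISSION = "inpatient_admission"
    TRANSFER = "transfer"
    DISCHARGE_HOME = "discharge_home"
    DEATH = "death"
    OTHER = "other"
    MISSING = "missing"


@dataclass(frozen=True, slots=True)
class DiagnosisEntry:
    """One ED diagnosis: an ICD-10-GM code plus its certainty qualifier."""

    code: ICDCode
    certainty: Certainty = Certainty.MISSING


@dataclass(slots=True)
class EDAttendance:
    """A single emergency-department attendance.

    ``age_group_lower`` is the lower bound of the 5-year age band
    (0, 5, ..., 95); ``triage`` is the 1-5 urgency level or ``None`` when
    missing; ``chief_complaint`` is a 3-digit CEDIS-PCL code or ``None``.
    """

    attendance_id: str
    ed_id: str
    admission_date: date
    age_group_lower: int
    sex: Sex
    triage: int | None = None
    chief_complaint: str | None = None
    diagnoses: list[DiagnosisEntry] = field(default_factory=list)
    disposition: Disposition = Disposition.MISSING

    def __post_init__(self) -> None:
        if self.age_group_lower < 0 or self.age_group_lower % 5:
            raise ValueError(
                f"age band lower bound must be a nonnegative multiple of 5, "
                f"got {self.age_group_lower}"
            )
        if self.triage is not None and self.triage not in (1, 2, 3, 4, 5):
            raise ValueError(f"triage must be 1..5 or None, got {self.triage}")


@dataclass(slots=True)
class InpatientRecord:
    """Discharge diagnoses for a hospitalized attendance.

    ``discharge_diagnoses`` is a list of ``(code, is_main)`` pairs with at
    least one entry and at most one main diagnosis.
    """

    attendance_id: str
    discharge_diagnoses: list[tuple[ICDCode, bool]]

    def __post_init__(self) -> None:
        if not self.discharge_diagnoses:
            raise ValueError(
                f"inpatient record {self.attendance_id} has no discharge diagnosis"
            )
        if sum(bool(m) for _, m in self.discharge_diagnoses) > 1:
            raise ValueError(
                f"inpatient record {self.attendance_id} has multiple main diagnoses"
            )

    @property
    def groups(self) -> set[str]:
        return {c.group for c, _ in self.discharge_diagnoses}


@dataclass(slots=True)
class LinkedCase:
    """An ED attendance joined to its inpatient discharge record."""

    attendance: EDAttendance
    inpatient: InpatientRecord

    def __post_init__(self) -> None:
        if self.attendance.attendance_id != self.inpatient.attendance_id:
            raise ValueError("attendance_id mismatch in linked case")


def link_cases(
    ed: Sequence[EDAttendance], inpatient: Sequence[InpatientRecord]
) -> list[LinkedCase]:
    """Case-level inner join of ED attendances and inpatient records.

    Keeps only attendances present in both datasets (i.e. ED patients who
    were admitted); output order follows the ED list.
    """
    by_id = {r.attendance_id: r for r in inpatient}
    return [
        LinkedCase(att, by_id[att.attendance_id])
        for att in ed
        if att.attendance_id in by_id
    ]


def collapse_age(age_group_lower: int) -> str:
    """Map a 5-year age-band lower bound to the 20-year analysis band."""
    if age_group_lower < 0:
        raise ValueError("age band lower bound must be >= 0")
    if age_group_lower < 20:
        return "0-19"
    if age_group_lower < 40:
        return "20-39"
    if age_group_lower < 60:
        return "40-59"
    if age_group_lower < 80:
        return "60-79"
    return "80+"


class HospitalStatTable:
    """Yearly aggregated hospital diagnosis counts.

    Mirrors the federal hospital diagnosis statistic: counts of discharge
    diagnoses by year x ICD group x 20-year age band x sex, with no
    case-level linkage possible.  Wraps a DataFrame with columns
    ``year, icd_group, age_band, sex, count``.
    """

    COLUMNS = ("year", "icd_group", "age_band", "sex", "count")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"hospital statistics table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(int)
        if (df["count"] < 0).any():
            raise ValueError("hospital statistics counts must be nonnegative")
        bad_band = set(df["age_band"]) - set(ANALYSIS_AGE_BANDS)
        if bad_band:
            raise ValueError(f"unknown age bands in hospital statistics: {bad_band}")
        bad_sex = set(df["sex"]) - {Sex.FEMALE.value, Sex.MALE.value}
        if bad_sex:
            raise ValueError(f"hospital statistics sex must be female/male, got {bad_sex}")
        keys = ["year", "icd_group", "age_band", "sex"]
        if df.duplicated(keys).any():
            raise ValueError("duplicate (year, icd_group, age_band, sex) rows")
        self.df = df.sort_values(keys, ignore_index=True)

    def __len__(self) -> int:
        return len(self.df)

    def counts_for_groups(
        self, groups: Iterable[str], years: Iterable[int]
    ) -> pd.DataFrame:
        """Sum counts over the given ICD groups and years, by stratum.

        Returns a DataFrame indexed by ``(age_band, sex)`` with a ``count``
        column; strata absent from the table get count 0 only if present in
        other groups (callers reindex as needed).
        """
        sel = self.df[
            self.df["icd_group"].isin(set(groups)) & self.df["year"].isin(set(years))
        ]
        return (
            sel.groupby(["age_band", "sex"], observed=True)["count"]
            .sum()
            .reset_index()
        )
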