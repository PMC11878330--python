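"""Descriptive baseline table: attendances by sex, age and triage level,
stratified by syndrome labels."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .records import EDAttendance, Sex, collapse_age

__all__ = ["descriptive_table", "column_percentage"]

_COLUMNS = ("acs", "mi", "str", "all")


def column_percentage(count: int, total: int) -> float:
    """Column percentage rounded to one decimal (counts stay unrounded)."""
    return round(100.0 * count / total, 1) if total else float("nan")


def descriptive_table(
    atts: Sequence[EDAttendance], labels: pd.DataFrame
) -> pd.DataFrame:
    """Counts and column percentages per stratum per indicator column.

    Rows: sex (female/male/other), 20-year age band, triage level 1-5 plus
    an explicit "missing" row.  Columns: a (count, pct) pair for each of
    ACS, MI, STR and all attendances.  Percentages are within-column (e.g.
    the share of ACS cases that are male) and rounded to one decimal.
    """
    if not set(a.attendance_id for a in atts) <= set(labels.index):
        raise ValueError("labels do not cover all attendances")
    base = pd.DataFrame(
        {
            "sex": [a.sex.value for a in atts],
            "age_band": [collapse_age(a.age_group_lower) for a in atts],
            "triage": [str(a.triage) if a.triage is not None else "missing" for a in atts],
        },
        index=pd.Index([a.attendance_id for a in atts], name="attendance_id"),
    )
    lab = labels.reindex(base.index)
    rows = []
    strata = (
        [("sex", s.value) for s in Sex]
        + [("age_band", b) for b in ("0-19", "20-39", "40-59", "60-79", "80+")]
        + [("triage", t) for t in ("1", "2", "3", "4", "5", "missing")]
    )
    totals = {c: (int(lab[c].sum()) if c != "all" else len(base)) for c in _COLUMNS}
    for section, value in strata:
        in_stratum = base[section] == value
        row: dict = {"section": section, "stratum": value}
        for col in _COLUMNS:
            cnt = int(in_stratum.sum()) if col == "all" else int((in_stratum & lab[col]).sum())
            row[f"{col}_count"] = cnt
            row[f"{col}_pct"] = column_percentage(cnt, totals[col])
        rows.append(row)
    return pd.DataFrame(rows)
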