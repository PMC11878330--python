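"""Published aggregate baseline counts used as a worked example.

A multicenter German ED registry study (nine EDs, January 2019 - March
2021, 704,797 attendances) published a baseline table of attendance counts
by sex, 20-year age band and triage level, stratified by the three
rule-based indicators.  The counts are bundled here as a small reference
input: they exercise the descriptive-percentage arithmetic end to end and
anchor the worked examples, since the underlying case-level registry data
are not redistributable.
"""

from __future__ import annotations

import pandas as pd

from .describe import column_percentage

__all__ = ["baseline_counts", "baseline_percentages", "TOTALS"]

#: total attendances per column (indicator positives and all attendances)
TOTALS = {"acs": 30_217, "mi": 4_155, "str": 22_642, "all": 704_797}

_ROWS = [
    # section, stratum, ACS, MI, STR, all
    ("sex", "female", 12_587, 1_465, 10_886, 333_392),
    ("sex", "male", 17_630, 2_690, 11_756, 371_405),
    ("age_band", "0-19", 0, 0, 0, 77_346),
    ("age_band", "20-39", 4_543, 177, 900, 172_443),
    ("age_band", "40-59", 8_244, 1_023, 3_862, 159_474),
    ("age_band", "60-79", 11_233, 1_901, 9_835, 176_233),
    ("age_band", "80+", 6_197, 1_054, 8_045, 119_301),
    ("triage", "1", 666, 146, 1_256, 8_669),
    ("triage", "2", 8_878, 1_583, 9_860, 94_107),
    ("triage", "3", 10_697, 1_331, 5_638, 203_535),
    ("triage", "4", 4_228, 327, 1_782, 270_973),
    ("triage", "5", 208, 14, 175, 31_534),
    ("triage", "missing", 5_540, 754, 3_931, 95_979),
]


def baseline_counts() -> pd.DataFrame:
    """The published stratified counts as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["section", "stratum", "acs", "mi", "str", "all"]
    )


def baseline_percentages() -> pd.DataFrame:
    """Column percentages recomputed from the published counts.

    Adds ``<col>_pct`` columns (one-decimal column percentages) to the
    counts, plus the overall indicator share of all attendances is exposed
    via :func:`indicator_share`.
    """
    df = baseline_counts()
    for col in ("acs", "mi", "str", "all"):
        df[f"{col}_pct"] = [column_percentage(c, TOTALS[col]) for c in df[col]]
    return df


def indicator_share(indicator: str) -> float:
    """Indicator positives as a one-decimal percentage of all attendances."""
    return column_percentage(TOTALS[indicator.lower()], TOTALS["all"])
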