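"""External validation against the aggregated hospital diagnosis statistics.

The yearly federal hospital statistic cannot be linked case by case, and
its absolute denominator (all German hospitals) is incomparable to a
handful of sentinel EDs.  The comparison therefore works on *relative* case
numbers: within each source, each (20-year age band x sex) stratum's share
of that source's total cases for the indicator.  Stratum-wise ratios of the
two shares, with 95% CIs on the log scale treating both shares as binomial
proportions (Katz method), quantify congruence — ratios near 1 mean the ED
sentinel reproduces the national age/sex distribution.

ED-side denominators are complete-case: attendances with missing sex are
dropped from numerator and denominator, and the comparison is restricted to
full calendar years.  The 0-19 band is excluded (the syndrome rules require
age >= 20, so its ED share is structurally zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    ANALYSIS_AGE_BANDS,
    EDAttendance,
    HospitalStatTable,
    Sex,
    collapse_age,
)
from .internal import DEFAULT_GOLD_GROUPS

__all__ = [
    "StratumShare",
    "RatioEstimate",
    "collapse_age",
    "stratum_shares",
    "hospital_stat_shares",
    "ratio_with_ci",
    "external_ratios",
    "ADULT_BANDS",
]

ADULT_BANDS = tuple(b for b in ANALYSIS_AGE_BANDS if b != "0-19")


@dataclass(frozen=True)
class StratumShare:
    source: str  # "ed" | "hospital_stat"
    indicator: str
    age_band: str
    sex: str
    count: int
    share: float


@dataclass(frozen=True)
class RatioEstimate:
    indicator: str
    age_band: str
    sex: str
    ratio: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.ratio <= self.ci_high + 1e-12):
            raise ValueError("ratio outside its confidence interval")


def _share_frame(counts: pd.Series, source: str, indicator: str) -> list[StratumShare]:
    total = int(counts.sum())
    return [
        StratumShare(
            source=source,
            indicator=indicator,
            age_band=band,
            sex=sex,
            count=int(c),
            share=(int(c) / total) if total else float("nan"),
        )
        for (band, sex), c in counts.items()
    ]


def stratum_shares(
    positives: Sequence[EDAttendance],
    indicator: str,
    restrict_years: Iterable[int],
    complete_case: bool = True,
) -> list[StratumShare]:
    """Age/sex stratum shares of ED syndrome-positive attendances.

    ``positives`` are the attendances labeled positive by the syndrome
    rule.  Counts are restricted to admission years in ``restrict_years``;
    with ``complete_case`` (default) attendances with missing sex are
    dropped from numerator and denominator alike.
    """
    years = set(restrict_years)
    if not years:
        raise ValueError("restrict_years must be nonempty")
    rows = [
        (collapse_age(a.age_group_lower), a.sex.value)
        for a in positives
        if a.admission_date.year in years
        and (not complete_case or a.sex in (Sex.FEMALE, Sex.MALE))
    ]
    idx = pd.MultiIndex.from_product(
        [list(ADULT_BANDS), [Sex.FEMALE.value, Sex.MALE.value]],
        names=["age_band", "sex"],
    )
    counts = (
        pd.Series(1, index=pd.MultiIndex.from_tuples(rows, names=["age_band", "sex"]))
        .groupby(level=[0, 1])
        .sum()
        .reindex(idx, fill_value=0)
        if rows
        else pd.Series(0, index=idx)
    )
    return _share_frame(counts, "ed", indicator)


def hospital_stat_shares(
    table: HospitalStatTable,
    indicator: str,
    restrict_years: Iterable[int],
    groups: dict | None = None,
) -> list[StratumShare]:
    """Stratum shares of the indicator's gold ICD groups in the yearly
    hospital statistics, summed over the given years."""
    groups = groups or DEFAULT_GOLD_GROUPS
    counts = table.counts_for_groups(groups[indicator], restrict_years)
    idx = pd.MultiIndex.from_product(
        [list(ADULT_BANDS), [Sex.FEMALE.value, Sex.MALE.value]],
        names=["age_band", "sex"],
    )
    series = (
        counts.set_index(["age_band", "sex"])["count"].reindex(idx, fill_value=0)
        if len(counts)
        else pd.Series(0, index=idx)
    )
    return _share_frame(series, "hospital_stat", indicator)


_Z975 = float(stats.norm.ppf(0.975))


def ratio_with_ci(ed: StratumShare, hosp: StratumShare) -> RatioEstimate:
    """Katz log-scale CI for the ratio of two binomial proportions.

    With p1 = x1/n1 (ED share) and p2 = x2/n2 (hospital-statistic share):

        R = p1 / p2,
        CI = exp( ln R +- z * sqrt((1-p1)/(n1 p1) + (1-p2)/(n2 p2)) ).

    A zero hospital share is undefined (raises); a zero ED share yields
    ratio 0 with a one-sided upper bound (ci_low 0).
    """
    if (ed.indicator, ed.age_band, ed.sex) != (hosp.indicator, hosp.age_band, hosp.sex):
        raise ValueError("ratio requires matching indicator/age band/sex strata")
    if hosp.share == 0 or np.isnan(hosp.share):
        raise ZeroDivisionError(
            f"hospital share is zero for stratum {ed.age_band}/{ed.sex}; ratio undefined"
        )
    if ed.count == 0:
        return RatioEstimate(ed.indicator, ed.age_band, ed.sex, 0.0, 0.0, float("inf"))
    p1, p2 = ed.share, hosp.share
    x1 = ed.count
    n1 = x1 / p1
    x2 = hosp.count
    n2 = x2 / p2
    se = np.sqrt((1 - p1) / (n1 * p1) + (1 - p2) / (n2 * p2))
    r = p1 / p2
    return RatioEstimate(
        indicator=ed.indicator,
        age_band=ed.age_band,
        sex=ed.sex,
        ratio=float(r),
        ci_low=float(r * np.exp(-_Z975 * se)),
        ci_high=float(r * np.exp(_Z975 * se)),
    )


def external_ratios(
    positives: Sequence[EDAttendance],
    table: HospitalStatTable,
    indicator: str,
    restrict_years: Iterable[int],
    complete_case: bool = True,
) -> pd.DataFrame:
    """Full stratified ED vs hospital-statistics comparison for one indicator.

    Returns one row per stratum: counts, shares, ratio and its 95% CI.
    Strata with an undefined ratio (zero hospital share) get NaN bounds.
    """
    ed_shares = stratum_shares(positives, indicator, restrict_years, complete_case)
    hosp_shares = hospital_stat_shares(table, indicator, restrict_years)
    rows = []
    for e, h in zip(ed_shares, hosp_shares):
        row = {
            "indicator": indicator,
            "age_band": e.age_band,
            "sex": e.sex,
            "ed_count": e.count,
            "ed_share": e.share,
            "hosp_count": h.count,
            "hosp_share": h.share,
        }
        try:
            est = ratio_with_ci(e, h)
            row |= {"ratio": est.ratio, "ci_low": est.ci_low, "ci_high": est.ci_high}
        except ZeroDivisionError:
            row |= {"ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan}
        rows.append(row)
    return pd.DataFrame(rows)
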