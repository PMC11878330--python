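"""Internal validation against linked hospital discharge diagnoses.

Among attendances that could be linked to an inpatient record, the hospital
discharge diagnosis serves as the reference standard: an attendance is a
true ACS case if any discharge diagnosis falls in group I20 or I21, a true
MI case for group I21, and a true stroke case for I60/I61/I63/I64.
Sensitivity, specificity and accuracy of the ED syndrome definitions are
estimated with exact 95% Clopper-Pearson intervals, discharge coding of the
ED-positive cases is tabulated, and the daily ED-identified and
discharge-identified case series are compared as 7-day moving averages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import LinkedCase

__all__ = [
    "GoldStandardSpec",
    "ConfusionMatrix",
    "MetricEstimate",
    "Metric",
    "gold_label",
    "gold_labels",
    "confusion",
    "metric_with_ci",
    "all_metrics",
    "top_discharge_groups",
    "case_series",
    "moving_average",
    "rolling_metrics",
    "clopper_pearson",
]

DEFAULT_GOLD_GROUPS: dict[str, frozenset[str]] = {
    "ACS": frozenset({"I20", "I21"}),
    "MI": frozenset({"I21"}),
    "STR": frozenset({"I60", "I61", "I63", "I64"}),
}


@dataclass(frozen=True)
class GoldStandardSpec:
    """Reference-standard ICD groups per indicator.

    ``scope`` selects whether any discharge diagnosis counts
    (``"any_diagnosis"``, the default) or only the flagged main diagnosis
    (``"main_only"``).
    """

    groups: Mapping[str, frozenset[str]] = None  # type: ignore[assignment]
    scope: str = "any_diagnosis"

    def __post_init__(self) -> None:
        if self.groups is None:
            object.__setattr__(self, "groups", dict(DEFAULT_GOLD_GROUPS))
        if self.scope not in ("any_diagnosis", "main_only"):
            raise ValueError(f"unknown gold-standard scope {self.scope!r}")


class Metric(str, enum.Enum):
    SENSITIVITY = "sensitivity"
    SPECIFICITY = "specificity"
    ACCURACY = "accuracy"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    metric: Metric
    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.value <= self.ci_high + 1e-12):
            raise ValueError("point estimate outside its confidence interval")


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is zero."""


def gold_label(case: LinkedCase, spec: GoldStandardSpec, indicator: str) -> bool:
    """Reference-standard label of one linked case."""
    groups = spec.groups[indicator]
    if spec.scope == "main_only":
        return any(
            main and code.group in groups
            for code, main in case.inpatient.discharge_diagnoses
        )
    return any(code.group in groups for code, _ in case.inpatient.discharge_diagnoses)


def gold_labels(
    cases: Sequence[LinkedCase],
    spec: GoldStandardSpec | None = None,
    indicators: Sequence[str] = ("ACS", "MI", "STR"),
) -> pd.DataFrame:
    """Reference-standard labels for all linked cases, one bool column per
    indicator (lowercased), indexed by attendance_id."""
    spec = spec or GoldStandardSpec()
    idx = pd.Index([c.attendance.attendance_id for c in cases], name="attendance_id")
    return pd.DataFrame(
        {ind.lower(): [gold_label(c, spec, ind) for c in cases] for ind in indicators},
        index=idx,
    )


def confusion(labels: pd.Series, gold: pd.Series) -> ConfusionMatrix:
    """2x2 cross-tabulation of ED labels against gold labels.

    Both series must be boolean and indexed by the same attendance-id set.
    """
    if set(labels.index) != set(gold.index):
        raise ValueError("labels and gold standard cover different attendance ids")
    gold = gold.reindex(labels.index)
    lab = labels.to_numpy(dtype=bool)
    gld = gold.to_numpy(dtype=bool)
    return ConfusionMatrix(
        tp=int((lab & gld).sum()),
        fp=int((lab & ~gld).sum()),
        fn=int((~lab & gld).sum()),
        tn=int((~lab & ~gld).sum()),
    )


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, beta-quantile form.

    lower = Beta(alpha/2; x, n-x+1), upper = Beta(1-alpha/2; x+1, n-x),
    with the conventional closures at x=0 and x=n.
    """
    if n <= 0:
        raise UndefinedMetricError("confidence interval needs n > 0")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def metric_with_ci(
    cm: ConfusionMatrix, metric: Metric | str, conf: float = 0.95
) -> MetricEstimate:
    """One diagnostic-accuracy metric with its exact binomial CI.

    sensitivity = tp / (tp + fn), specificity = tn / (tn + fp),
    accuracy = (tp + tn) / n.  A zero denominator raises
    :class:`UndefinedMetricError` rather than returning NaN.
    """
    metric = Metric(metric)
    if metric is Metric.SENSITIVITY:
        x, n = cm.tp, cm.tp + cm.fn
    elif metric is Metric.SPECIFICITY:
        x, n = cm.tn, cm.tn + cm.fp
    else:
        x, n = cm.tp + cm.tn, cm.n
    if n == 0:
        raise UndefinedMetricError(f"{metric.value} undefined: denominator is zero")
    low, high = clopper_pearson(x, n, conf)
    return MetricEstimate(
        metric=metric, value=x / n, ci_low=low, ci_high=high,
        numerator=x, denominator=n,
    )


def all_metrics(cm: ConfusionMatrix, conf: float = 0.95) -> dict[str, MetricEstimate]:
    return {m.value: metric_with_ci(cm, m, conf) for m in Metric}


def top_discharge_groups(cases: Sequence[LinkedCase], k: int = 10) -> pd.DataFrame:
    """The k most common discharge diagnosis groups among syndrome-positive
    linked cases.

    The counting unit is the case: a case contributes once per distinct
    group even when several subcodes of that group are coded.  Proportions
    are over all cases passed in; ties rank lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for case in cases:
        for g in sorted(case.inpatient.groups):
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["icd_group", "count", "proportion"])
    df = (
        pd.DataFrame(
            {"icd_group": list(counts), "count": list(counts.values())}
        )
        .sort_values(["count", "icd_group"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )
    df["proportion"] = df["count"] / len(cases)
    return df


def case_series(
    dates: Sequence[date], period: tuple[date, date]
) -> pd.Series:
    """Daily case counts over the full study period, with explicit zeros."""
    idx = pd.date_range(period[0], period[1], freq="D")
    counts = pd.Series(pd.to_datetime(list(dates))).value_counts()
    return counts.reindex(idx, fill_value=0).astype(int).rename("cases")


def moving_average(series: pd.Series, window: int = 7) -> pd.Series:
    """Trailing (right-aligned) moving average; the first ``window - 1``
    points are NaN.  A trailing window is the real-time surveillance
    convention — a centered window would need future data."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return series.rolling(window, min_periods=window).mean()


def rolling_metrics(
    labels: pd.Series,
    gold: pd.Series,
    dates: Mapping[str, date],
    conf: float = 0.95,
) -> pd.DataFrame:
    """Sensitivity and specificity per calendar month.

    ``dates`` maps attendance_id to admission date.  A month with a zero
    denominator gets NaN for that metric and ``defined`` False; the run
    continues.
    """
    if set(labels.index) != set(gold.index):
        raise ValueError("labels and gold standard cover different attendance ids")
    month = pd.PeriodIndex(
        [pd.Timestamp(dates[i]) for i in labels.index], freq="M"
    )
    rows = []
    frame = pd.DataFrame({"label": labels, "gold": gold.reindex(labels.index)})
    for per, sub in frame.groupby(month):
        cm = confusion(sub["label"], sub["gold"])
        row: dict = {"period": str(per), "n": cm.n, "defined": True}
        for metric in (Metric.SENSITIVITY, Metric.SPECIFICITY):
            try:
                est = metric_with_ci(cm, metric, conf)
                row[metric.value] = est.value
                row[f"{metric.value}_low"] = est.ci_low
                row[f"{metric.value}_high"] = est.ci_high
            except UndefinedMetricError:
                row[metric.value] = np.nan
                row[f"{metric.value}_low"] = np.nan
                row[f"{metric.value}_high"] = np.nan
                row["defined"] = False
        rows.append(row)
    return pd.DataFrame(rows)
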