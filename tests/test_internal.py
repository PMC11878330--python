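"""Internal validation: gold standard, confusion metrics with exact CIs,
discharge tabulation, time series."""

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

import edsynd as e
from edsynd.internal import Metric, UndefinedMetricError
from edsynd.simulate import IndicatorParams


def _linked(discharges, main_first=True):
    att = e.EDAttendance("A1", "ED01", date(2020, 1, 1), 60, e.Sex.MALE)
    dx = [
        (e.normalize_icd(c), main_first and i == 0) for i, c in enumerate(discharges)
    ]
    return e.LinkedCase(att, e.InpatientRecord("A1", dx))


class TestGoldLabel:
    spec = e.GoldStandardSpec()

    @pytest.mark.parametrize(
        "codes, indicator, expect",
        [
            (["I21.0", "J18.9"], "MI", True),
            (["R07.4"], "ACS", False),
            (["G45.9"], "STR", False),  # TIA is not in the stroke gold set
            (["I20.0"], "ACS", True),
            (["I63.4"], "STR", True),
            (["I20.0"], "MI", False),
        ],
    )
    def test_examples(self, codes, indicator, expect):
        assert e.gold_label(_linked(codes), self.spec, indicator) is expect

    def test_main_only_scope(self):
        case = _linked(["J18.9", "I21.0"])  # I21 is secondary
        assert e.gold_label(case, self.spec, "MI")
        assert not e.gold_label(case, e.GoldStandardSpec(scope="main_only"), "MI")


class TestConfusion:
    def test_all_true(self):
        idx = [f"A{i}" for i in range(5)]
        lab = pd.Series(True, index=idx)
        cm = e.confusion(lab, lab.copy())
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 0)

    def test_complement_labels(self):
        idx = ["A0", "A1", "A2", "A3"]
        gold = pd.Series([True, True, False, False], index=idx)
        cm = e.confusion(~gold, gold)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 2, 2, 0)

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different"):
            e.confusion(pd.Series([True], index=["A0"]), pd.Series([True], index=["B0"]))

    def test_matches_pairwise_count_on_cohort(self, midsize):
        lab = midsize["labels"].loc[midsize["gold"].index, "acs"]
        gold = midsize["gold"]["acs"]
        cm = e.confusion(lab, gold)
        tp = fp = fn = tn = 0
        for i in lab.index:
            a, g = bool(lab[i]), bool(gold[i])
            tp += a and g
            fp += a and not g
            fn += g and not a
            tn += not a and not g
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)
        assert cm.n == len(lab)


class TestMetricWithCI:
    def test_boundary_perfect_sensitivity(self):
        cm = e.ConfusionMatrix(tp=10, fp=0, fn=0, tn=5)
        est = e.metric_with_ci(cm, "sensitivity")
        assert est.value == 1.0 and est.ci_high == 1.0 and est.ci_low < 1.0

    def test_zero_denominator_is_explicit(self):
        cm = e.ConfusionMatrix(tp=0, fp=3, fn=0, tn=7)
        with pytest.raises(UndefinedMetricError):
            e.metric_with_ci(cm, "sensitivity")

    @pytest.mark.parametrize("x, n", [(8, 10), (0, 20), (20, 20), (1, 7), (150, 400)])
    def test_clopper_pearson_matches_independent_implementation(self, x, n):
        low, high = e.clopper_pearson(x, n)
        sm_low, sm_high = proportion_confint(x, n, alpha=0.05, method="beta")
        assert low == pytest.approx(sm_low, abs=1e-10)
        assert high == pytest.approx(sm_high, abs=1e-10)

    def test_accuracy_identity_holds_exactly(self, midsize):
        """accuracy = (sens*P + spec*N) / (P+N) on every computed matrix."""
        for ind in ("ACS", "MI", "STR"):
            lab = midsize["labels"].loc[midsize["gold"].index, ind.lower()]
            cm = e.confusion(lab, midsize["gold"][ind.lower()])
            sens = cm.tp / (cm.tp + cm.fn)
            spec = cm.tn / (cm.tn + cm.fp)
            pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
            acc = e.metric_with_ci(cm, "accuracy").value
            assert acc == pytest.approx((sens * pos + spec * neg) / (pos + neg), abs=1e-12)


class TestTopDischargeGroups:
    def test_direct_count(self):
        cases = [_linked([c]) for c in ("I21.0", "I21.4", "R07.4", "I20.0")]
        top = e.top_discharge_groups(cases, k=3)
        assert top["icd_group"].tolist() == ["I21", "I20", "R07"]
        assert top["proportion"].tolist() == [0.5, 0.25, 0.25]

    def test_k_larger_than_distinct_groups(self):
        cases = [_linked(["I21.0"]), _linked(["I63.4"])]
        assert len(e.top_discharge_groups(cases, k=10)) == 2

    def test_case_counted_once_per_group(self):
        cases = [_linked(["I21.0", "I21.4"])]
        top = e.top_discharge_groups(cases, k=5)
        assert top.loc[0, "count"] == 1

    def test_empty_input(self):
        assert len(e.top_discharge_groups([], k=5)) == 0

    def test_mi_positive_cases_lead_with_i21_at_expected_rate(self, midsize):
        """Among ED-identified MI cases, the expected share with an I21
        discharge equals the generator's positive predictive value."""
        lab = midsize["labels"].loc[midsize["gold"].index, "mi"]
        pos = [c for c in midsize["linked"] if bool(lab[c.attendance.attendance_id])]
        top = e.top_discharge_groups(pos, k=1)
        assert top.loc[0, "icd_group"] == "I21"
        expected = e.expected_ppv(midsize["config"], "MI")
        se = (expected * (1 - expected) / len(pos)) ** 0.5
        assert abs(top.loc[0, "proportion"] - expected) < 3 * se


class TestSeries:
    period = (date(2020, 1, 1), date(2020, 1, 10))

    def test_constant_series_has_constant_moving_average(self):
        s = pd.Series(10.0, index=pd.date_range(*self.period))
        ma = e.moving_average(s, 7)
        assert ma.iloc[:6].isna().all()
        assert (ma.iloc[6:] == 10.0).all()

    def test_single_burst_moving_average(self):
        s = pd.Series([0, 0, 0, 0, 0, 0, 7, 0, 0, 0], index=pd.date_range(*self.period), dtype=float)
        ma = e.moving_average(s, 7)
        assert ma.iloc[6] == 1.0

    def test_case_series_has_explicit_zeros(self):
        s = e.case_series([date(2020, 1, 3), date(2020, 1, 3)], self.period)
        assert len(s) == 10
        assert s.sum() == 2
        assert s.loc["2020-01-05"] == 0

    def test_ed_and_gold_series_show_dip_and_correlate(self, config_factory):
        """Under a high-sensitivity config both the ED-identified and the
        discharge-identified daily series show the dip, and their 7-day
        moving averages are strongly correlated."""
        cfg = config_factory(
            n_eds=3, daily_rate_per_ed=150.0,
            start=date(2020, 1, 1), end=date(2020, 6, 30),
            dip_start=date(2020, 3, 10), dip_end=date(2020, 4, 19),
            dip_multiplier=0.5,
            indicators={
                "ACS": IndicatorParams(0.13, 0.95, 0.05, 0.005, 0.0, 0.95),
                "MI": IndicatorParams(0.01, 0.95, 0.05, 0.001, 0.0, 0.95),
                "STR": IndicatorParams(0.12, 0.95, 0.05, 0.005, 0.0, 0.95),
            },
        )
        bundle = e.generate_cohort(cfg, seed=21)
        labels = e.classify_cohort(bundle.attendances)
        linked = e.link_cases(bundle.attendances, bundle.inpatient)
        gold = e.gold_labels(linked)
        dates = {a.attendance_id: a.admission_date for a in bundle.attendances}
        ed_ma = e.moving_average(
            e.case_series([dates[i] for i in labels.index[labels["str"]]], cfg.period)
        )
        gold_ma = e.moving_average(
            e.case_series([dates[i] for i in gold.index[gold["str"]]], cfg.period)
        )
        both = pd.DataFrame({"ed": ed_ma, "gold": gold_ma}).dropna()
        assert both["ed"].corr(both["gold"]) > 0.9
        in_dip = [cfg.trend.dip_start <= d.date() <= cfg.trend.dip_end for d in both.index]
        for col in ("ed", "gold"):
            assert both.loc[in_dip, col].mean() < 0.75 * both.loc[[not x for x in in_dip], col].mean()


class TestRollingMetrics:
    def test_single_period_equals_global(self, midsize):
        gold = midsize["gold"]["acs"]
        lab = midsize["labels"].loc[gold.index, "acs"]
        dates = {
            a.attendance_id: date(2020, 2, 15) for a in midsize["bundle"].attendances
        }
        rolled = e.rolling_metrics(lab, gold, dates)
        assert len(rolled) == 1
        cm = e.confusion(lab, gold)
        assert rolled.loc[0, "sensitivity"] == pytest.approx(
            e.metric_with_ci(cm, "sensitivity").value
        )
        assert rolled.loc[0, "specificity"] == pytest.approx(
            e.metric_with_ci(cm, "specificity").value
        )

    def test_zero_gold_positive_month_flagged_not_fatal(self):
        idx = ["A0", "A1", "A2", "A3"]
        lab = pd.Series([True, False, False, True], index=idx)
        gold = pd.Series([True, False, False, False], index=idx)
        dates = {
            "A0": date(2020, 1, 5), "A1": date(2020, 1, 9),
            "A2": date(2020, 2, 5), "A3": date(2020, 2, 9),  # no gold positives in Feb
        }
        rolled = e.rolling_metrics(lab, gold, dates)
        feb = rolled[rolled["period"] == "2020-02"].iloc[0]
        assert np.isnan(feb["sensitivity"]) and not feb["defined"]
        jan = rolled[rolled["period"] == "2020-01"].iloc[0]
        assert jan["defined"] and jan["sensitivity"] == 1.0

    def test_monthly_sensitivity_stays_within_band_of_global(self, midsize):
        """Under a stationary generator the per-month sensitivity CI covers
        the global estimate in at least 90% of months."""
        gold = midsize["gold"]["acs"]
        lab = midsize["labels"].loc[gold.index, "acs"]
        dates = {a.attendance_id: a.admission_date for a in midsize["bundle"].attendances}
        rolled = e.rolling_metrics(lab, gold, dates)
        global_sens = e.metric_with_ci(e.confusion(lab, gold), "sensitivity").value
        ok = (
            (rolled["sensitivity_low"] <= global_sens)
            & (global_sens <= rolled["sensitivity_high"])
        )
        assert ok.mean() >= 0.9
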