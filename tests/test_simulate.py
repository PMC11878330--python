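"""Synthetic cohort generator: reproducibility, degenerate configs,
Poisson/dip structure, aggregation consistency, and the analytic oracles."""

import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

import edsynd as e
from edsynd.records import collapse_age, Sex
from edsynd.simulate import GOLD_GROUPS, IndicatorParams, Missingness, Trend


def _filecmp(a, b):
    return a.read_bytes() == b.read_bytes()


def test_same_seed_byte_identical_csv(config_factory, tmp_path):
    cfg = config_factory(seed=3, daily_rate_per_ed=15.0, end=date(2020, 4, 30))
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    e.generate_cohort(cfg).write(d1)
    e.generate_cohort(cfg).write(d2)
    for name in ("ed.csv", "inpatient.csv", "hospital_stats.csv", "truth.csv"):
        assert _filecmp(d1 / name, d2 / name), name


def test_different_seeds_differ(config_factory):
    cfg = config_factory(daily_rate_per_ed=10.0, end=date(2020, 2, 29),
                         dip_start=date(2020, 2, 1), dip_end=date(2020, 2, 14))
    b1 = e.generate_cohort(cfg, seed=1)
    b2 = e.generate_cohort(cfg, seed=2)
    assert [a.diagnoses for a in b1.attendances] != [a.diagnoses for a in b2.attendances]


def test_zero_prevalence_zero_noise_yields_no_cases(config_factory):
    cfg = config_factory(
        daily_rate_per_ed=30.0,
        end=date(2020, 3, 31),
        dip_start=date(2020, 3, 1), dip_end=date(2020, 3, 14),
        indicators={
            k: IndicatorParams(0.0, 0.5, 0.2, 0.0, 0.0, 0.9) for k in ("ACS", "MI", "STR")
        },
    )
    bundle = e.generate_cohort(cfg, seed=4)
    labels = e.classify_cohort(bundle.attendances)
    assert int(labels.to_numpy().sum()) == 0
    assert not bundle.truth.to_numpy().any()
    assert len(bundle.hospital_stats) == 0


def test_stationary_mean_daily_count(config_factory):
    """With no dip and no weekly seasonality, daily totals are Poisson
    around n_eds x daily_rate (checked within 3 standard errors)."""
    cfg = config_factory(
        n_eds=3, daily_rate_per_ed=50.0,
        start=date(2020, 1, 1), end=date(2020, 12, 31),
        dip_start=date(2020, 6, 1), dip_end=date(2020, 6, 2),
        dip_multiplier=1.0, weekly_amplitude=0.0,
    )
    bundle = e.generate_cohort(cfg, seed=5)
    counts = pd.Series([a.admission_date for a in bundle.attendances]).value_counts()
    counts = counts.reindex(pd.date_range(*cfg.period).date, fill_value=0)
    lam = cfg.n_eds * cfg.daily_rate_per_ed
    se = (lam / len(counts)) ** 0.5
    assert abs(counts.mean() - lam) < 3 * se


def test_dip_window_scales_mean_attendance(config_factory):
    """Mean daily attendance inside the dip window is ~multiplier x the
    mean outside it."""
    cfg = config_factory(
        n_eds=2, daily_rate_per_ed=100.0,
        start=date(2020, 1, 1), end=date(2020, 12, 31),
        dip_start=date(2020, 3, 15), dip_end=date(2020, 4, 30),
        dip_multiplier=0.6, weekly_amplitude=0.0,
    )
    bundle = e.generate_cohort(cfg, seed=6)
    dates = pd.Series([a.admission_date for a in bundle.attendances])
    counts = dates.value_counts().reindex(pd.date_range(*cfg.period).date, fill_value=0)
    in_dip = pd.Series(
        [cfg.trend.dip_start <= d <= cfg.trend.dip_end for d in counts.index],
        index=counts.index,
    )
    mean_in, mean_out = counts[in_dip].mean(), counts[~in_dip].mean()
    k_in, k_out = int(in_dip.sum()), int((~in_dip).sum())
    m = cfg.trend.dip_multiplier
    se = np.sqrt(mean_in / k_in + m**2 * mean_out / k_out)
    assert abs(mean_in - m * mean_out) < 3 * se


def test_hospital_stats_equal_groupby_over_inpatient_records(midsize):
    """Aggregation consistency: the emitted yearly table equals an
    independent record-level group-by over the inpatient gold codes."""
    bundle = midsize["bundle"]
    by_id = {a.attendance_id: a for a in bundle.attendances}
    all_gold = set().union(*GOLD_GROUPS.values())
    rows = []
    for rec in bundle.inpatient:
        att = by_id[rec.attendance_id]
        if att.sex not in (Sex.FEMALE, Sex.MALE):
            continue
        for group in sorted(rec.groups & all_gold):
            rows.append(
                (att.admission_date.year, group, collapse_age(att.age_group_lower), att.sex.value)
            )
    expected = (
        pd.DataFrame(rows, columns=["year", "icd_group", "age_band", "sex"])
        .groupby(["year", "icd_group", "age_band", "sex"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["year", "icd_group", "age_band", "sex"], ignore_index=True)
    )
    pd.testing.assert_frame_equal(bundle.hospital_stats.df, expected)


def test_every_inpatient_id_has_an_attendance(midsize):
    ed_ids = {a.attendance_id for a in midsize["bundle"].attendances}
    assert all(r.attendance_id in ed_ids for r in midsize["bundle"].inpatient)
    assert len(midsize["bundle"].truth) == len(midsize["bundle"].attendances)


class TestExpectedMetrics:
    def test_forced_perfect_sensitivity(self, config_factory):
        cfg = config_factory(
            indicators={
                "ACS": IndicatorParams(0.02, 1.0, 0.0, 0.01, 0.0, 0.9),
                "MI": IndicatorParams(0.01, 1.0, 0.0, 0.001, 0.0, 0.9),
                "STR": IndicatorParams(0.02, 1.0, 0.0, 0.01, 0.0, 0.9),
            },
        )
        for ind in ("ACS", "MI", "STR"):
            sens, _ = e.expected_metrics(cfg, ind)
            assert sens == pytest.approx(1.0)

    def test_forced_perfect_specificity(self, config_factory):
        cfg = config_factory(
            indicators={
                "ACS": IndicatorParams(0.02, 0.7, 0.1, 0.0, 0.0, 0.9),
                "MI": IndicatorParams(0.01, 0.6, 0.2, 0.0, 0.0, 0.9),
                "STR": IndicatorParams(0.02, 0.7, 0.1, 0.0, 0.0, 0.9),
            },
        )
        for ind in ("ACS", "MI", "STR"):
            _, specificity = e.expected_metrics(cfg, ind)
            assert specificity == pytest.approx(1.0)

    def test_half_specific_fifth_complaint_gives_seventy_percent(self, config_factory):
        """p_specific=0.5 and p_complaint_only=0.2 with no complaint masking
        compose to sensitivity 0.70 among linked cases, cross-checked
        against a 10^6-draw Monte-Carlo of the documentation model."""
        params = IndicatorParams(0.05, 0.5, 0.2, 0.0, 0.0, 0.9)
        cfg = config_factory(
            indicators={"ACS": params, "MI": dataclasses.replace(params, prevalence=0.0),
                        "STR": params},
            missingness=Missingness(chief_complaint=0.0),
        )
        sens, _ = e.expected_metrics(cfg, "STR")
        assert sens == pytest.approx(0.7)

        rng = np.random.default_rng(12345)
        n = 1_000_000
        u = rng.random(n)
        fires = (u < 0.5) | ((u >= 0.5) & (u < 0.7))  # dx branch, else complaint seen
        mc = fires.mean()
        se = (0.7 * 0.3 / n) ** 0.5
        assert abs(mc - sens) < 3 * se

    def test_complaint_masking_discounts_complaint_branch(self, config_factory):
        cfg = config_factory(missingness=Missingness(chief_complaint=0.2))
        sens, _ = e.expected_metrics(cfg, "STR")
        p = cfg.indicators["STR"]
        assert sens == pytest.approx(p.p_specific_dx + p.p_complaint_only * 0.8)

    def test_mi_sensitivity_is_specific_dx_only(self, config_factory):
        cfg = config_factory()
        sens, _ = e.expected_metrics(cfg, "MI")
        assert sens == pytest.approx(cfg.indicators["MI"].p_specific_dx)


class TestConfigValidation:
    def test_demographics_must_sum_to_one(self, config_factory):
        cfg = config_factory()
        bad = dataclasses.replace(cfg, demographics={(20, "male"): 0.5})
        with pytest.raises(ValueError, match="sum"):
            bad.validate()

    def test_dip_window_must_lie_in_period(self, config_factory):
        cfg = config_factory()
        bad = dataclasses.replace(
            cfg, trend=Trend(dip_start=date(2031, 1, 1), dip_end=date(2031, 2, 1))
        )
        with pytest.raises(ValueError, match="dip window"):
            bad.validate()

    def test_mi_prevalence_cannot_exceed_acs(self, config_factory):
        cfg = config_factory()
        bad_ind = dict(cfg.indicators)
        bad_ind["MI"] = dataclasses.replace(bad_ind["MI"], prevalence=0.5)
        with pytest.raises(ValueError, match="subgroup"):
            dataclasses.replace(cfg, indicators=bad_ind).validate()

    def test_probability_bounds_enforced(self, config_factory):
        cfg = config_factory()
        bad_ind = dict(cfg.indicators)
        bad_ind["STR"] = dataclasses.replace(bad_ind["STR"], p_specific_dx=1.4)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dataclasses.replace(cfg, indicators=bad_ind).validate()


def test_generator_config_yaml_round_trip(config_factory, tmp_path):
    cfg = config_factory(seed=9, hosp_rate_modifiers={("20-39", "female"): 0.4})
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = e.GeneratorConfig.from_yaml(path)
    assert back.indicators == cfg.indicators
    assert back.trend == cfg.trend
    assert back.hosp_rate_modifiers == cfg.hosp_rate_modifiers
    assert back.period == cfg.period
    assert back.demographics.keys() == cfg.demographics.keys()
    assert all(
        back.demographics[k] == pytest.approx(cfg.demographics[k])
        for k in cfg.demographics
    )
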