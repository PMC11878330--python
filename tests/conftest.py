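"""Shared fixtures: scaled generator configs, a mid-size cohort, and an
independent brute-force re-implementation of the syndrome definitions used
as the oracle for classifier-equivalence tests."""

from __future__ import annotations

import dataclasses
from datetime import date

import pytest
from hypothesis import HealthCheck, settings

import edsynd as e
from edsynd.simulate import Trend

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def scaled_config(
    seed: int = 0,
    n_eds: int = 2,
    daily_rate_per_ed: float = 60.0,
    start: date = date(2020, 1, 1),
    end: date = date(2020, 6, 30),
    dip_start: date = date(2020, 3, 10),
    dip_end: date = date(2020, 4, 19),
    dip_multiplier: float = 0.65,
    weekly_amplitude: float = 0.15,
    **overrides,
):
    """The study-shaped default config scaled down for test runtimes."""
    cfg = e.default_config(seed=seed)
    cfg = dataclasses.replace(
        cfg,
        n_eds=n_eds,
        daily_rate_per_ed=daily_rate_per_ed,
        period=(start, end),
        trend=Trend(
            weekly_amplitude=weekly_amplitude,
            dip_start=dip_start,
            dip_end=dip_end,
            dip_multiplier=dip_multiplier,
        ),
        **overrides,
    )
    return cfg


@pytest.fixture(scope="session")
def config_factory():
    return scaled_config


@pytest.fixture(scope="session")
def rules():
    return e.builtin_rules()


@pytest.fixture(scope="session")
def midsize():
    """~22k-attendance cohort with labels, linkage and gold standard."""
    cfg = scaled_config(seed=11)
    bundle = e.generate_cohort(cfg)
    labels = e.classify_cohort(bundle.attendances)
    linked = e.link_cases(bundle.attendances, bundle.inpatient)
    gold = e.gold_labels(linked)
    return {
        "config": cfg,
        "bundle": bundle,
        "labels": labels,
        "linked": linked,
        "gold": gold,
    }


# ---------------------------------------------------------------------------
# brute-force rule oracle: plain nested conditionals, written directly from
# the clinical definitions and kept independent of edsynd.rules internals
# ---------------------------------------------------------------------------

_INCLUDABLE = ("confirmed", "suspected", "missing")
_SEVERE = ("inpatient_admission", "death", "other", "missing")


def _brute_acs(att) -> bool:
    if att.age_group_lower < 20:
        return False
    for d in att.diagnoses:
        if d.certainty.value not in _INCLUDABLE:
            continue
        c = d.code.raw
        g = c[:3]
        if g in ("I20", "I21"):
            return True
        if g == "R07" and c != "R07.0":
            return True
        if c.startswith("R57.0"):
            return True
    if att.diagnoses:
        return False
    if att.chief_complaint in ("001", "003", "004"):
        return att.disposition.value in _SEVERE
    return False


def _brute_mi(att) -> bool:
    if att.age_group_lower < 20:
        return False
    for d in att.diagnoses:
        if d.certainty.value in _INCLUDABLE and d.code.raw[:3] == "I21":
            return True
    return False


def _brute_str(att) -> bool:
    if att.age_group_lower < 20:
        return False
    for d in att.diagnoses:
        if d.certainty.value in _INCLUDABLE and d.code.raw[:3] in ("I60", "I61", "I63", "I64"):
            return True
    if att.diagnoses:
        return False
    if att.chief_complaint == "409":
        return att.disposition.value in _SEVERE
    return False


BRUTE_ORACLE = {"ACS": _brute_acs, "MI": _brute_mi, "STR": _brute_str}


@pytest.fixture(scope="session")
def brute_oracle():
    return BRUTE_ORACLE
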