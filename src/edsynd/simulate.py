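"""Seeded synthetic ED cohort generator with closed-form oracles.

The generator emulates the statistical structure of case-based German ED
surveillance extracts: daily attendance counts with weekly seasonality and a
pandemic-style dip, coarse demographics, a latent per-attendance case status
for the three indicators (ACS, MI as a subgroup of ACS, and stroke),
imperfect ED documentation (a specific rule-matching diagnosis, a
rule-matching chief complaint only, or nothing indicator-specific),
disposition/hospitalization behavior, and field missingness.  Hospitalized
attendances emit an inpatient discharge record whose codes realize the gold
standard exactly: a true case always carries its indicator's discharge
group, a non-case never does.  A yearly aggregated hospital-statistics table
is derived from the emitted discharge codes.

Because the generative probabilities are explicit, the operating
characteristics of the shipped syndrome definitions on a generated cohort
have closed forms (:func:`expected_metrics`, :func:`expected_positive_share`,
:func:`expected_stratum_shares`), which downstream estimates must recover.

Modeling conventions (see docs/methods.md for rationale):

* latent indicator status is a single mutually exclusive draw per adult
  attendance from {none, ACS-only, MI, STR}; an MI case is always an ACS
  case; attendances under 20 are structural non-cases;
* attendances documented complaint-only (true cases) or with a
  false-positive complaint (non-cases) carry no coded ED diagnoses, so the
  complaint branch of the rules — which requires absence of any ED
  diagnosis — can actually fire;
* daily counts are Poisson with a cosine day-of-week factor (mean 1 over a
  week) times the dip multiplier inside the dip window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import (
    Certainty,
    DiagnosisEntry,
    Disposition,
    EDAttendance,
    HospitalStatTable,
    InpatientRecord,
    Sex,
    collapse_age,
)
from .codes import normalize_icd
from . import io as edio

__all__ = [
    "IndicatorParams",
    "Missingness",
    "Trend",
    "GeneratorConfig",
    "CohortBundle",
    "default_config",
    "generate_cohort",
    "expected_metrics",
    "expected_positive_share",
    "expected_linked_fraction",
    "expected_ppv",
    "expected_stratum_shares",
]

# ---------------------------------------------------------------------------
# code pools
# ---------------------------------------------------------------------------

# rule-matching ED diagnoses for ACS cases that are not MI (angina, chest
# pain other than throat pain, cardiogenic shock)
ACS_ONLY_ED_DX = ["I20.0", "I20.1", "I20.8", "I20.9", "R07.1", "R07.2", "R07.3", "R07.4", "R57.0"]
MI_ED_DX = ["I21.0", "I21.1", "I21.2", "I21.3", "I21.4", "I21.9"]
STR_ED_DX = ["I63.0", "I63.3", "I63.4", "I63.5", "I63.9", "I61.0", "I61.9", "I60.9", "I64"]

# irrelevant ED noise diagnoses; deliberately includes R07.0 (throat pain,
# excluded from the ACS rule) and G45.9 (TIA, not in the stroke rule)
IRRELEVANT_ED_DX = [
    "J06.9", "J18.9", "A09.9", "K52.9", "S06.0", "M54.5", "R10.4",
    "R51", "R55", "F10.0", "T78.4", "Z03.9", "R07.0", "G45.9",
]

# gold-standard discharge codes by latent state
ACS_ONLY_GOLD_DX = ["I20.0", "I20.8", "I20.9"]
MI_GOLD_DX = ["I21.0", "I21.1", "I21.4", "I21.9"]
STR_GOLD_DX = ["I63.0", "I63.4", "I63.5", "I63.9", "I61.0", "I61.9", "I60.9", "I64"]
STR_GOLD_WEIGHTS = [0.18, 0.18, 0.18, 0.23, 0.07, 0.07, 0.04, 0.05]

# discharge codes that never touch a gold group (non-cases, and secondary
# codes of true cases)
NONCASE_DISCHARGE_DX = [
    "R07.4", "J18.9", "A09.9", "K52.9", "S06.0", "F10.0", "I50.9",
    "J44.1", "N39.0", "K80.2", "R55", "G45.9", "M54.5", "E11.9",
]
CASE_SECONDARY_DISCHARGE_DX = ["E11.9", "I10.00", "N39.0", "J44.1", "E78.5"]

ACS_COMPLAINTS = ["001", "003", "004"]
ACS_COMPLAINT_WEIGHTS = [0.05, 0.60, 0.35]
STR_COMPLAINT = "409"
UNSPECIFIC_COMPLAINTS = ["002", "006", "050", "251", "351", "401", "455", "651", "703", "755"]

GOLD_GROUPS = {"ACS": {"I20", "I21"}, "MI": {"I21"}, "STR": {"I60", "I61", "I63", "I64"}}

_LATENT_NONE, _LATENT_ACS_ONLY, _LATENT_MI, _LATENT_STR = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class IndicatorParams:
    """Generative parameters for one indicator.

    prevalence
        P(latent case | adult attendance).  For ACS this includes MI.
    p_specific_dx
        P(case receives a rule-matching ED diagnosis | case).
    p_complaint_only
        P(case is documented only by a rule-matching chief complaint, with
        no coded ED diagnosis | case).  The remainder is documented
        unspecifically.
    p_false_dx
        P(non-case receives a rule-matching ED diagnosis | adult non-case).
    p_false_complaint
        P(non-case receives a rule-matching chief complaint and no ED
        diagnosis | adult non-case).
    p_hosp_case
        P(hospitalized | case), before any stratum modifier.
    """

    prevalence: float
    p_specific_dx: float
    p_complaint_only: float
    p_false_dx: float
    p_false_complaint: float
    p_hosp_case: float

    def validate(self, name: str) -> None:
        for f_name in ("prevalence", "p_specific_dx", "p_complaint_only",
                       "p_false_dx", "p_false_complaint", "p_hosp_case"):
            _check_prob(getattr(self, f_name), f"{name}.{f_name}")
        if self.p_specific_dx + self.p_complaint_only > 1.0 + 1e-12:
            raise ValueError(f"{name}: p_specific_dx + p_complaint_only > 1")


@dataclass(frozen=True)
class Missingness:
    """Per-field masking probabilities (applied after generation)."""

    triage: float = 0.136
    disposition: float = 0.03
    certainty: float = 0.10
    chief_complaint: float = 0.05

    def validate(self) -> None:
        for f_name in ("triage", "disposition", "certainty", "chief_complaint"):
            _check_prob(getattr(self, f_name), f"missingness.{f_name}")


@dataclass(frozen=True)
class Trend:
    """Weekly seasonality amplitude and a multiplicative dip window."""

    weekly_amplitude: float = 0.15
    dip_start: date = date(2020, 3, 10)
    dip_end: date = date(2020, 4, 19)
    dip_multiplier: float = 0.65

    def validate(self, period: tuple[date, date]) -> None:
        if not (0.0 <= self.weekly_amplitude < 1.0):
            raise ValueError("trend.weekly_amplitude must be in [0, 1)")
        if not (0.0 < self.dip_multiplier <= 1.0):
            raise ValueError("trend.dip_multiplier must be in (0, 1]")
        if self.dip_start > self.dip_end:
            raise ValueError("trend dip window start after end")
        if self.dip_start < period[0] or self.dip_end > period[1]:
            raise ValueError("trend dip window outside the study period")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator.

    ``demographics`` maps ``(age_band_lower, sex_value)`` to a probability;
    the table must sum to one.  ``hosp_rate_modifiers`` maps
    ``(analysis_age_band, sex_value)`` to a multiplier applied to
    ``p_hosp_case`` for true cases in that stratum (used to create
    deliberate ED-vs-hospital-statistics divergence).
    """

    n_eds: int
    period: tuple[date, date]
    daily_rate_per_ed: float
    demographics: dict[tuple[int, str], float]
    indicators: dict[str, IndicatorParams]
    p_hosp_noncase: float
    certainty_weights_case: dict[str, float]
    certainty_weights_noise: dict[str, float]
    missingness: Missingness = field(default_factory=Missingness)
    triage_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.014, 2: 0.155, 3: 0.334, 4: 0.445, 5: 0.052}
    )
    nonhosp_disposition: dict[str, float] = field(
        default_factory=lambda: {
            "discharge_home": 0.85, "transfer": 0.05, "other": 0.05,
            "death": 0.01, "missing": 0.04,
        }
    )
    noise_dx_rate: float = 0.60
    unspecific_complaint_rate: float = 0.80
    trend: Trend = field(default_factory=Trend)
    hosp_rate_modifiers: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_eds < 1:
            raise ValueError("n_eds must be >= 1")
        if self.daily_rate_per_ed <= 0:
            raise ValueError("daily_rate_per_ed must be positive")
        if self.period[0] > self.period[1]:
            raise ValueError("period start after end")
        total = sum(self.demographics.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"demographics probabilities sum to {total}, not 1")
        for (age, sex), p in self.demographics.items():
            _check_prob(p, f"demographics[{age},{sex}]")
            if age < 0 or age % 5:
                raise ValueError(f"demographics age band {age} not a multiple of 5")
            Sex(sex)
        for name in ("ACS", "MI", "STR"):
            if name not in self.indicators:
                raise ValueError(f"missing indicator params for {name}")
            self.indicators[name].validate(name)
        acs, mi, stroke = (self.indicators[k] for k in ("ACS", "MI", "STR"))
        if mi.prevalence > acs.prevalence:
            raise ValueError("MI prevalence exceeds ACS prevalence (MI is a subgroup of ACS)")
        if acs.prevalence + stroke.prevalence > 1.0:
            raise ValueError("total indicator prevalence exceeds 1")
        noise_total = (
            acs.p_false_dx + mi.p_false_dx + stroke.p_false_dx
            + acs.p_false_complaint + stroke.p_false_complaint
        )
        if noise_total > 1.0:
            raise ValueError("false-signal probabilities sum above 1")
        _check_prob(self.p_hosp_noncase, "p_hosp_noncase")
        _check_prob(self.noise_dx_rate, "noise_dx_rate")
        _check_prob(self.unspecific_complaint_rate, "unspecific_complaint_rate")
        for dist, name in (
            (self.certainty_weights_case, "certainty_weights_case"),
            (self.certainty_weights_noise, "certainty_weights_noise"),
            (self.triage_dist, "triage_dist"),
            (self.nonhosp_disposition, "nonhosp_disposition"),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        bad = set(self.certainty_weights_case) - {"confirmed", "suspected", "missing"}
        if bad:
            raise ValueError(
                f"case certainty weights may only cover confirmed/suspected/missing, got {bad}"
            )
        self.missingness.validate()
        self.trend.validate(self.period)
        for (band, sex), m in self.hosp_rate_modifiers.items():
            if m < 0:
                raise ValueError(f"hosp_rate_modifiers[{band},{sex}] negative")

    # -- serialization (YAML mirrors the dataclass field-for-field) --------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["period"] = [self.period[0].isoformat(), self.period[1].isoformat()]
        d["demographics"] = [
            {"age_group_lower": a, "sex": s, "prob": p}
            for (a, s), p in sorted(self.demographics.items())
        ]
        d["trend"] = {
            "weekly_amplitude": self.trend.weekly_amplitude,
            "dip_start": self.trend.dip_start.isoformat(),
            "dip_end": self.trend.dip_end.isoformat(),
            "dip_multiplier": self.trend.dip_multiplier,
        }
        d["hosp_rate_modifiers"] = [
            {"age_band": b, "sex": s, "multiplier": m}
            for (b, s), m in sorted(self.hosp_rate_modifiers.items())
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_eds=int(d["n_eds"]),
            period=(date.fromisoformat(d["period"][0]), date.fromisoformat(d["period"][1])),
            daily_rate_per_ed=float(d["daily_rate_per_ed"]),
            demographics={
                (int(r["age_group_lower"]), r["sex"]): float(r["prob"])
                for r in d["demographics"]
            },
            indicators={k: IndicatorParams(**v) for k, v in d["indicators"].items()},
            p_hosp_noncase=float(d["p_hosp_noncase"]),
            certainty_weights_case=dict(d["certainty_weights_case"]),
            certainty_weights_noise=dict(d["certainty_weights_noise"]),
            missingness=Missingness(**d.get("missingness", {})),
            triage_dist=(
                {int(k): float(v) for k, v in d["triage_dist"].items()}
                if d.get("triage_dist")
                else cls.__dataclass_fields__["triage_dist"].default_factory()
            ),
            nonhosp_disposition=dict(
                d.get(
                    "nonhosp_disposition",
                    cls.__dataclass_fields__["nonhosp_disposition"].default_factory(),
                )
            ),
            noise_dx_rate=float(d.get("noise_dx_rate", 0.60)),
            unspecific_complaint_rate=float(d.get("unspecific_complaint_rate", 0.80)),
            trend=Trend(
                weekly_amplitude=float(d["trend"]["weekly_amplitude"]),
                dip_start=date.fromisoformat(d["trend"]["dip_start"]),
                dip_end=date.fromisoformat(d["trend"]["dip_end"]),
                dip_multiplier=float(d["trend"]["dip_multiplier"]),
            )
            if "trend" in d
            else Trend(),
            hosp_rate_modifiers={
                (r["age_band"], r["sex"]): float(r["multiplier"])
                for r in d.get("hosp_rate_modifiers", [])
            },
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(seed: int = 0) -> GeneratorConfig:
    """Default generator configuration.

    Emulates the conditions of a nine-ED German registry extract over
    2019-01-01..2021-03-05 (~98.5 attendances/ED/day, ~705k attendances):
    demographics matching the observed age margins (11% under 20, heaviest
    load at 60-79), prevalence and documentation probabilities chosen so
    that the shipped rules see roughly 4-5% ACS, 0.6-0.7% MI and ~3.3%
    stroke positives among all attendances, sensitivities near 85/57/80%,
    specificities near 96/99.7/98%, and ~42% of attendances hospitalized.
    A spring-2020 dip (multiplier 0.65) emulates the pandemic-onset drop in
    attendance.
    """
    age_dist = {
        0: 0.020, 5: 0.025, 10: 0.030, 15: 0.035,
        20: 0.065, 25: 0.065, 30: 0.060, 35: 0.055,
        40: 0.055, 45: 0.055, 50: 0.057, 55: 0.059,
        60: 0.060, 65: 0.062, 70: 0.063, 75: 0.065,
        80: 0.065, 85: 0.055, 90: 0.030, 95: 0.019,
    }
    sex_dist = {"male": 0.525, "female": 0.471, "other": 0.004}
    demographics = {
        (a, s): round(pa * ps, 12)
        for a, pa in age_dist.items()
        for s, ps in sex_dist.items()
    }
    # exact renormalization against rounding residue
    total = sum(demographics.values())
    demographics = {k: v / total for k, v in demographics.items()}
    return GeneratorConfig(
        n_eds=9,
        period=(date(2019, 1, 1), date(2021, 3, 5)),
        daily_rate_per_ed=98.5,
        demographics=demographics,
        indicators={
            "ACS": IndicatorParams(0.016, 0.75, 0.15, 0.040, 0.010, 0.85),
            "MI": IndicatorParams(0.008, 0.57, 0.25, 0.004, 0.000, 0.92),
            "STR": IndicatorParams(0.026, 0.66, 0.15, 0.018, 0.006, 0.90),
        },
        p_hosp_noncase=0.40,
        certainty_weights_case={"confirmed": 0.55, "suspected": 0.25, "missing": 0.20},
        certainty_weights_noise={
            "confirmed": 0.30, "suspected": 0.20, "excluded": 0.15,
            "status_post": 0.05, "missing": 0.30,
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """A generated cohort: attendances, inpatient records, aggregated
    hospital statistics, and the latent per-attendance truth labels."""

    attendances: list[EDAttendance]
    inpatient: list[InpatientRecord]
    hospital_stats: HospitalStatTable
    truth: pd.DataFrame  # indexed by attendance_id, bool columns acs/mi/str
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as the four CSV files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ed": outdir / "ed.csv",
            "inpatient": outdir / "inpatient.csv",
            "hospital_stats": outdir / "hospital_stats.csv",
            "truth": outdir / "truth.csv",
        }
        edio.write_ed_table(self.attendances, paths["ed"])
        edio.write_inpatient_table(self.inpatient, paths["inpatient"])
        edio.write_hospital_stats(self.hospital_stats, paths["hospital_stats"])
        self.truth.to_csv(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _weekday_factors(amplitude: float) -> np.ndarray:
    # cosine over the 7 weekdays; the 7 equally spaced cosine values sum to
    # zero, so the factors average exactly 1 over a full week
    return 1.0 + amplitude * np.cos(2.0 * np.pi * np.arange(7) / 7.0)


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> CohortBundle:
    """Draw a full synthetic cohort; reproducible given the seed.

    ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    start, end = config.period
    n_days = (end - start).days + 1
    days = [start + timedelta(days=i) for i in range(n_days)]
    dow = np.array([d.weekday() for d in days])
    factors = _weekday_factors(config.trend.weekly_amplitude)[dow]
    dip = np.array(
        [config.trend.dip_start <= d <= config.trend.dip_end for d in days]
    )
    lam = config.n_eds * config.daily_rate_per_ed * factors
    lam = np.where(dip, lam * config.trend.dip_multiplier, lam)
    n_per_day = rng.poisson(lam)
    n = int(n_per_day.sum())
    day_idx = np.repeat(np.arange(n_days), n_per_day)

    # demographics
    demo_rows = sorted(config.demographics.items())
    demo_age = np.array([a for (a, _), _ in demo_rows])
    demo_sex = np.array([s for (_, s), _ in demo_rows])
    demo_p = np.array([p for _, p in demo_rows])
    stratum = rng.choice(len(demo_rows), size=n, p=demo_p)
    age = demo_age[stratum]
    sex = demo_sex[stratum]
    adult = age >= 20

    # latent indicator state (mutually exclusive; adults only)
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    pi_mi, pi_acs_only, pi_str = (
        mi.prevalence, acs.prevalence - mi.prevalence, stroke.prevalence,
    )
    u = rng.random(n)
    latent = np.zeros(n, dtype=np.int8)
    latent[adult & (u < pi_mi)] = _LATENT_MI
    latent[adult & (u >= pi_mi) & (u < pi_mi + pi_acs_only)] = _LATENT_ACS_ONLY
    latent[adult & (u >= pi_mi + pi_acs_only) & (u < pi_mi + pi_acs_only + pi_str)] = _LATENT_STR
    is_case = latent != _LATENT_NONE

    # documentation mode for cases
    p_spec = np.array([0.0, acs.p_specific_dx, mi.p_specific_dx, stroke.p_specific_dx])
    p_compl = np.array([0.0, acs.p_complaint_only, mi.p_complaint_only, stroke.p_complaint_only])
    v = rng.random(n)
    doc_specific = is_case & (v < p_spec[latent])
    doc_complaint = is_case & ~doc_specific & (v < (p_spec + p_compl)[latent])

    # noise signal for non-cases: exactly one of
    # {false dx ACS, false dx MI, false dx STR, false complaint ACS,
    #  false complaint STR, nothing}
    cum = np.cumsum(
        [acs.p_false_dx, mi.p_false_dx, stroke.p_false_dx,
         acs.p_false_complaint, stroke.p_false_complaint]
    )
    w = rng.random(n)
    noise_cat = np.searchsorted(cum, w).astype(np.int8)  # 0..4 signal, 5 nothing
    noise_cat[is_case] = 5

    # hospitalization
    p_hosp_case = np.array([0.0, acs.p_hosp_case, mi.p_hosp_case, stroke.p_hosp_case])
    ph = np.where(is_case, p_hosp_case[latent], config.p_hosp_noncase)
    if config.hosp_rate_modifiers:
        mod_per_stratum = np.array(
            [
                config.hosp_rate_modifiers.get((collapse_age(a), s), 1.0)
                for (a, s), _ in demo_rows
            ]
        )
        ph = np.where(is_case, np.minimum(1.0, ph * mod_per_stratum[stratum]), ph)
    hosp = rng.random(n) < ph

    # disposition
    nh_labels = list(config.nonhosp_disposition)
    nh_p = np.array([config.nonhosp_disposition[k] for k in nh_labels])
    nh_draw = rng.choice(len(nh_labels), size=n, p=nh_p)
    disposition = np.array(
        [Disposition.INPATIENT_ADMISSION.value] * n, dtype=object
    )
    nonhosp = ~hosp
    nh_values = np.array([Disposition(lbl).value for lbl in nh_labels], dtype=object)
    disposition[nonhosp] = nh_values[nh_draw[nonhosp]]
    disposition[rng.random(n) < config.missingness.disposition] = Disposition.MISSING.value

    # triage
    t_levels = sorted(config.triage_dist)
    t_p = np.array([config.triage_dist[k] for k in t_levels])
    triage = np.array(t_levels)[rng.choice(len(t_levels), size=n, p=t_p)].astype(float)
    triage[rng.random(n) < config.missingness.triage] = np.nan

    # chief complaint
    compl_acs = (doc_complaint & ((latent == _LATENT_ACS_ONLY) | (latent == _LATENT_MI))) | (
        noise_cat == 3
    )
    compl_str = (doc_complaint & (latent == _LATENT_STR)) | (noise_cat == 4)
    complaint = np.full(n, None, dtype=object)
    n_ca = int(compl_acs.sum())
    complaint[compl_acs] = rng.choice(ACS_COMPLAINTS, size=n_ca, p=ACS_COMPLAINT_WEIGHTS)
    complaint[compl_str] = STR_COMPLAINT
    plain = ~(compl_acs | compl_str)
    has_unspec = plain & (rng.random(n) < config.unspecific_complaint_rate)
    complaint[has_unspec] = rng.choice(UNSPECIFIC_COMPLAINTS, size=int(has_unspec.sum()))
    complaint[rng.random(n) < config.missingness.chief_complaint] = None

    # ED diagnoses
    case_cert_labels = list(config.certainty_weights_case)
    case_cert_p = np.array([config.certainty_weights_case[k] for k in case_cert_labels])
    noise_cert_labels = list(config.certainty_weights_noise)
    noise_cert_p = np.array([config.certainty_weights_noise[k] for k in noise_cert_labels])
    cert_mask = rng.random(n) < config.missingness.certainty
    cert_mask2 = rng.random(n) < config.missingness.certainty  # for a second dx

    def _sample_codes(mask: np.ndarray, pool: list[str]) -> np.ndarray:
        out = np.full(n, None, dtype=object)
        k = int(mask.sum())
        if k:
            out[mask] = rng.choice(pool, size=k)
        return out

    spec_code = np.full(n, None, dtype=object)
    for lat, pool in (
        (_LATENT_ACS_ONLY, ACS_ONLY_ED_DX),
        (_LATENT_MI, MI_ED_DX),
        (_LATENT_STR, STR_ED_DX),
    ):
        m = doc_specific & (latent == lat)
        spec_code[m] = _sample_codes(m, pool)[m]
    spec_cert = np.full(n, None, dtype=object)
    m = doc_specific
    spec_cert[m] = np.array(case_cert_labels, dtype=object)[
        rng.choice(len(case_cert_labels), size=int(m.sum()), p=case_cert_p)
    ]

    false_code = np.full(n, None, dtype=object)
    for cat, pool in ((0, ACS_ONLY_ED_DX), (1, MI_ED_DX), (2, STR_ED_DX)):
        m = noise_cat == cat
        false_code[m] = _sample_codes(m, pool)[m]
    has_false_dx = noise_cat <= 2
    false_cert = np.full(n, None, dtype=object)
    false_cert[has_false_dx] = np.array(noise_cert_labels, dtype=object)[
        rng.choice(len(noise_cert_labels), size=int(has_false_dx.sum()), p=noise_cert_p)
    ]

    complaint_designated = compl_acs | compl_str
    has_irrelevant = ~complaint_designated & (rng.random(n) < config.noise_dx_rate)
    irr_code = _sample_codes(has_irrelevant, IRRELEVANT_ED_DX)
    irr_cert = np.full(n, None, dtype=object)
    irr_cert[has_irrelevant] = np.array(noise_cert_labels, dtype=object)[
        rng.choice(len(noise_cert_labels), size=int(has_irrelevant.sum()), p=noise_cert_p)
    ]

    # discharge diagnoses for hospitalized attendances
    gold_code = np.full(n, None, dtype=object)
    for lat, pool, weights in (
        (_LATENT_ACS_ONLY, ACS_ONLY_GOLD_DX, None),
        (_LATENT_MI, MI_GOLD_DX, None),
        (_LATENT_STR, STR_GOLD_DX, STR_GOLD_WEIGHTS),
    ):
        m = hosp & (latent == lat)
        k = int(m.sum())
        if k:
            gold_code[m] = rng.choice(pool, size=k, p=weights)
    has_secondary = hosp & is_case & (rng.random(n) < 0.5)
    secondary_code = _sample_codes(has_secondary, CASE_SECONDARY_DISCHARGE_DX)
    noncase_hosp = hosp & ~is_case
    noncase_primary = _sample_codes(noncase_hosp, NONCASE_DISCHARGE_DX)
    noncase_has_second = noncase_hosp & (rng.random(n) < 0.3)
    noncase_second = _sample_codes(noncase_has_second, NONCASE_DISCHARGE_DX)

    # assemble typed records
    ed_ids = [f"ED{k + 1:02d}" for k in range(config.n_eds)]
    ed_assign = rng.choice(config.n_eds, size=n)
    cert_enum = {c.value: c for c in Certainty}
    code_cache: dict[str, object] = {}

    def _code(raw: str):
        c = code_cache.get(raw)
        if c is None:
            c = normalize_icd(raw)
            code_cache[raw] = c
        return c

    attendances: list[EDAttendance] = []
    inpatient: list[InpatientRecord] = []
    for i in range(n):
        dx: list[DiagnosisEntry] = []
        if spec_code[i] is not None:
            c = Certainty.MISSING if cert_mask[i] else cert_enum[spec_cert[i]]
            dx.append(DiagnosisEntry(_code(spec_code[i]), c))
        if false_code[i] is not None:
            c = Certainty.MISSING if cert_mask[i] else cert_enum[false_cert[i]]
            dx.append(DiagnosisEntry(_code(false_code[i]), c))
        if irr_code[i] is not None:
            c = Certainty.MISSING if cert_mask2[i] else cert_enum[irr_cert[i]]
            dx.append(DiagnosisEntry(_code(irr_code[i]), c))
        att_id = f"A{i:07d}"
        attendances.append(
            EDAttendance(
                attendance_id=att_id,
                ed_id=ed_ids[ed_assign[i]],
                admission_date=days[day_idx[i]],
                age_group_lower=int(age[i]),
                sex=Sex(sex[i]),
                triage=None if np.isnan(triage[i]) else int(triage[i]),
                chief_complaint=complaint[i],
                diagnoses=dx,
                disposition=Disposition(disposition[i]),
            )
        )
        if hosp[i]:
            ddx: list[tuple] = []
            if gold_code[i] is not None:
                ddx.append((_code(gold_code[i]), True))
                if secondary_code[i] is not None:
                    ddx.append((_code(secondary_code[i]), False))
            else:
                ddx.append((_code(noncase_primary[i]), True))
                if noncase_second[i] is not None:
                    ddx.append((_code(noncase_second[i]), False))
            inpatient.append(InpatientRecord(attendance_id=att_id, discharge_diagnoses=ddx))

    truth = pd.DataFrame(
        {
            "acs": (latent == _LATENT_ACS_ONLY) | (latent == _LATENT_MI),
            "mi": latent == _LATENT_MI,
            "str": latent == _LATENT_STR,
        },
        index=pd.Index([a.attendance_id for a in attendances], name="attendance_id"),
    )

    # yearly hospital statistics from the emitted gold-standard discharge codes
    stat_mask = hosp & is_case & ((sex == "female") | (sex == "male"))
    stats_df = pd.DataFrame(
        {
            "year": [days[d].year for d in day_idx[stat_mask]],
            "icd_group": [str(g)[:3] for g in gold_code[stat_mask]],
            "age_band": [collapse_age(int(a)) for a in age[stat_mask]],
            "sex": sex[stat_mask],
        }
    )
    if len(stats_df):
        stats_df = (
            stats_df.groupby(["year", "icd_group", "age_band", "sex"])
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        stats_df = pd.DataFrame(columns=list(HospitalStatTable.COLUMNS))
    return CohortBundle(
        attendances=attendances,
        inpatient=inpatient,
        hospital_stats=HospitalStatTable(stats_df),
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------


def _includable_noise_certainty(config: GeneratorConfig) -> float:
    # a noise diagnosis triggers a rule only with certainty confirmed,
    # suspected or missing; certainty masking maps any draw to missing,
    # which is itself includable:
    #   P(includable) = m_cert + (1 - m_cert) * (w_conf + w_susp + w_miss)
    w = config.certainty_weights_noise
    inc = w.get("confirmed", 0.0) + w.get("suspected", 0.0) + w.get("missing", 0.0)
    return config.missingness.certainty + (1 - config.missingness.certainty) * inc


def _adult_fraction(config: GeneratorConfig) -> float:
    return sum(p for (a, _), p in config.demographics.items() if a >= 20)


def _effective_hosp_case(config: GeneratorConfig, params: IndicatorParams) -> float:
    """E over adult strata of min(1, p_hosp_case * modifier)."""
    if not config.hosp_rate_modifiers:
        return params.p_hosp_case
    f_a = _adult_fraction(config)
    total = 0.0
    for (a, s), p in config.demographics.items():
        if a < 20:
            continue
        m = config.hosp_rate_modifiers.get((collapse_age(a), s), 1.0)
        total += (p / f_a) * min(1.0, params.p_hosp_case * m)
    return total


def _latent_masses(config: GeneratorConfig) -> dict[str, float]:
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    f_a = _adult_fraction(config)
    return {
        "f_y": 1 - f_a,
        "f_a": f_a,
        "pi_mi": mi.prevalence,
        "pi_acs_only": acs.prevalence - mi.prevalence,
        "pi_str": stroke.prevalence,
        "pi_none": 1 - acs.prevalence - stroke.prevalence,
        "ph_acs": _effective_hosp_case(config, acs),
        "ph_mi": _effective_hosp_case(config, mi),
        "ph_str": _effective_hosp_case(config, stroke),
    }


def expected_metrics(config: GeneratorConfig, indicator: str) -> tuple[float, float]:
    """Closed-form expected (sensitivity, specificity) among linked cases.

    Among hospitalized (= linked) attendances the recorded disposition is
    "inpatient admission" or masked to missing — both includable for the
    complaint branch — so disposition never truncates the complaint branch
    there.  With ``c = 1 - P(chief complaint masked)``:

    * sensitivity(MI)  = p_specific_dx                          (no complaint branch)
    * sensitivity(STR) = p_specific_dx + p_complaint_only * c
    * sensitivity(ACS) = weighted mix of the MI-latent and ACS-only-latent
      branches, weights proportional to prevalence x hospitalization of each
      latent state (an MI case's I21 diagnosis and chest-pain complaints
      both satisfy the ACS rule);

    * 1 - specificity = FP mass / gold-negative mass, where only adult
      latent-none attendances can produce a false positive:
      FP(none) = p_false_dx_effective * P(noise certainty includable)
               + p_false_complaint * c,
      with p_false_dx_effective(ACS) = p_false_dx(ACS) + p_false_dx(MI)
      (an I21 noise diagnosis fires the ACS rule too).  Gold-negative mass
      adds under-20 attendances and, per indicator, the hospitalized cases
      of the other latent states (which by construction never carry this
      indicator's codes or complaints).
    """
    config.validate()
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    m = _latent_masses(config)
    c = 1 - config.missingness.chief_complaint
    inc_noise = _includable_noise_certainty(config)

    sens_mi_branch = mi.p_specific_dx + mi.p_complaint_only * c  # vs the ACS rule
    sens_acs_branch = acs.p_specific_dx + acs.p_complaint_only * c
    mass_mi = m["f_a"] * m["pi_mi"] * m["ph_mi"]
    mass_acs_only = m["f_a"] * m["pi_acs_only"] * m["ph_acs"]
    mass_str = m["f_a"] * m["pi_str"] * m["ph_str"]
    mass_none = m["f_a"] * m["pi_none"] * config.p_hosp_noncase
    mass_young = m["f_y"] * config.p_hosp_noncase

    if indicator == "ACS":
        sens = (mass_mi * sens_mi_branch + mass_acs_only * sens_acs_branch) / (
            mass_mi + mass_acs_only
        )
        fp_none = (acs.p_false_dx + mi.p_false_dx) * inc_noise + acs.p_false_complaint * c
        goldneg = mass_young + mass_none + mass_str
    elif indicator == "MI":
        sens = mi.p_specific_dx
        fp_none = mi.p_false_dx * inc_noise
        goldneg = mass_young + mass_none + mass_acs_only + mass_str
    elif indicator == "STR":
        sens = stroke.p_specific_dx + stroke.p_complaint_only * c
        fp_none = stroke.p_false_dx * inc_noise + stroke.p_false_complaint * c
        goldneg = mass_young + mass_none + mass_acs_only + mass_mi
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    specificity = 1 - mass_none * fp_none / goldneg
    return float(sens), float(specificity)


def _disp_includable(config: GeneratorConfig, p_hosp: float) -> float:
    """P(recorded disposition is in the complaint branch's includable set).

    disposition = inpatient admission (if hospitalized) else a draw from the
    non-hospitalized distribution; masking maps any value to missing.
    Includable: inpatient admission, death, other, missing.
    """
    d = config.nonhosp_disposition
    nh_inc = d.get("death", 0.0) + d.get("other", 0.0) + d.get("missing", 0.0)
    md = config.missingness.disposition
    return md + (1 - md) * (p_hosp + (1 - p_hosp) * nh_inc)


def _case_rule_prob(config: GeneratorConfig, params: IndicatorParams, p_hosp: float,
                    complaint_branch: bool) -> float:
    """P(rule fires | latent case of a state the rule's codes cover)."""
    c = 1 - config.missingness.chief_complaint
    q = params.p_specific_dx
    if complaint_branch:
        q += params.p_complaint_only * c * _disp_includable(config, p_hosp)
    return q


def _noise_rule_prob(config: GeneratorConfig, indicator: str) -> float:
    """P(rule fires | adult latent-none attendance), any disposition."""
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    c = 1 - config.missingness.chief_complaint
    inc = _includable_noise_certainty(config)
    disp = _disp_includable(config, config.p_hosp_noncase)
    if indicator == "ACS":
        return (acs.p_false_dx + mi.p_false_dx) * inc + acs.p_false_complaint * c * disp
    if indicator == "MI":
        return mi.p_false_dx * inc
    if indicator == "STR":
        return stroke.p_false_dx * inc + stroke.p_false_complaint * c * disp
    raise ValueError(f"unknown indicator {indicator!r}")


def expected_positive_share(config: GeneratorConfig, indicator: str) -> float:
    """Expected fraction of ALL attendances labeled positive by the rule."""
    config.validate()
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    m = _latent_masses(config)
    noise = m["pi_none"] * _noise_rule_prob(config, indicator)
    if indicator == "ACS":
        case = m["pi_mi"] * _case_rule_prob(config, mi, m["ph_mi"], True) + m[
            "pi_acs_only"
        ] * _case_rule_prob(config, acs, m["ph_acs"], True)
    elif indicator == "MI":
        case = m["pi_mi"] * mi.p_specific_dx
    elif indicator == "STR":
        case = m["pi_str"] * _case_rule_prob(config, stroke, m["ph_str"], True)
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    return float(m["f_a"] * (case + noise))


def expected_linked_fraction(config: GeneratorConfig) -> float:
    """Expected fraction of attendances with an inpatient record."""
    config.validate()
    m = _latent_masses(config)
    return float(
        m["f_y"] * config.p_hosp_noncase
        + m["f_a"]
        * (
            m["pi_none"] * config.p_hosp_noncase
            + m["pi_mi"] * m["ph_mi"]
            + m["pi_acs_only"] * m["ph_acs"]
            + m["pi_str"] * m["ph_str"]
        )
    )


def expected_ppv(config: GeneratorConfig, indicator: str) -> float:
    """Expected positive predictive value among linked rule positives.

    Equals the expected proportion of rule-positive linked cases whose
    discharge record contains the indicator's gold-standard group (e.g. the
    expected top-discharge-group share of I21 among MI positives).
    """
    sens, specificity = expected_metrics(config, indicator)
    m = _latent_masses(config)
    mass_mi = m["f_a"] * m["pi_mi"] * m["ph_mi"]
    mass_acs_only = m["f_a"] * m["pi_acs_only"] * m["ph_acs"]
    mass_str = m["f_a"] * m["pi_str"] * m["ph_str"]
    mass_none = m["f_a"] * m["pi_none"] * config.p_hosp_noncase
    mass_young = m["f_y"] * config.p_hosp_noncase
    gold = {
        "ACS": mass_mi + mass_acs_only,
        "MI": mass_mi,
        "STR": mass_str,
    }[indicator]
    total = mass_mi + mass_acs_only + mass_str + mass_none + mass_young
    tp = gold * sens
    fp = (total - gold) * (1 - specificity)
    return float(tp / (tp + fp))


def expected_stratum_shares(config: GeneratorConfig, indicator: str) -> pd.DataFrame:
    """Expected ED vs hospital-statistics stratum shares and their ratio.

    Strata are the adult 20-year analysis bands x {female, male} (matching
    the complete-case ED denominator and the hospital statistics, which
    carry binary sex only).  ED share: expected rule positives per stratum /
    total.  Hospital share: expected gold discharge counts per stratum /
    total.  Returns columns ``age_band, sex, ed_share, hosp_share, ratio``.
    """
    config.validate()
    acs, mi, stroke = (config.indicators[k] for k in ("ACS", "MI", "STR"))
    rows = []
    for (a, s), p in sorted(config.demographics.items()):
        if a < 20 or s == "other":
            continue
        band = collapse_age(a)
        mods = config.hosp_rate_modifiers
        ph_acs = min(1.0, acs.p_hosp_case * mods.get((band, s), 1.0)) if mods else acs.p_hosp_case
        ph_mi = min(1.0, mi.p_hosp_case * mods.get((band, s), 1.0)) if mods else mi.p_hosp_case
        ph_str = min(1.0, stroke.p_hosp_case * mods.get((band, s), 1.0)) if mods else stroke.p_hosp_case
        pi_none = 1 - acs.prevalence - stroke.prevalence
        pi_acs_only = acs.prevalence - mi.prevalence
        noise = pi_none * _noise_rule_prob(config, indicator)
        if indicator == "ACS":
            case = mi.prevalence * _case_rule_prob(config, mi, ph_mi, True) + pi_acs_only * _case_rule_prob(
                config, acs, ph_acs, True
            )
            hosp_rate = mi.prevalence * ph_mi + pi_acs_only * ph_acs
        elif indicator == "MI":
            case = mi.prevalence * mi.p_specific_dx
            hosp_rate = mi.prevalence * ph_mi
        elif indicator == "STR":
            case = stroke.prevalence * _case_rule_prob(config, stroke, ph_str, True)
            hosp_rate = stroke.prevalence * ph_str
        else:
            raise ValueError(f"unknown indicator {indicator!r}")
        rows.append(
            {"age_band": band, "sex": s, "ed": p * (case + noise), "hosp": p * hosp_rate}
        )
    df = pd.DataFrame(rows).groupby(["age_band", "sex"], as_index=False).sum()
    df["ed_share"] = df["ed"] / df["ed"].sum()
    df["hosp_share"] = df["hosp"] / df["hosp"].sum()
    df["ratio"] = df["ed_share"] / df["hosp_share"]
    return df[["age_band", "sex", "ed_share", "hosp_share", "ratio"]]
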