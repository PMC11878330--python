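# Methods

## Problem and approach

`edsynd` implements a validation pipeline for rule-based syndromic
surveillance of three acute cardiovascular/cerebrovascular indicators in
German emergency-department (ED) routine data: acute coronary syndrome
(ACS), myocardial infarction (MI, a subgroup of ACS), and stroke (STR).
An ED attendance record carries coarse demographics (5-year age band,
sex), a triage urgency level, a CEDIS-PCL chief complaint, zero or more
ICD-10-GM diagnoses with certainty qualifiers, and a disposition.  A
*syndrome definition* is a deterministic rule over these fields that labels
the attendance a case.  Validity is assessed two ways:

* **internal** — attendances linked case-by-case to inpatient discharge
  records; the discharge diagnosis is the reference standard (ACS: any
  discharge code in groups I20/I21; MI: I21; STR: I60/I61/I63/I64), and
  sensitivity/specificity/accuracy are estimated with exact 95%
  Clopper–Pearson intervals;
* **external** — the age/sex distribution of ED cases is compared with the
  yearly aggregated national hospital diagnosis statistics through
  stratum-share ratios with Katz log-scale 95% intervals.

Because real registry extracts are not redistributable, a seeded synthetic
cohort generator stands in for the data source.  Its generative
probabilities are explicit, so the operating characteristics that the
pipeline should recover have closed forms, which all recovery tests use as
ground truth.

## Syndrome definitions

All three rules require the age-band lower bound to be ≥ 20 years.  The
cutoff is 20 rather than 18 because age arrives only in 5-year bands.
Diagnosis certainty qualifiers "confirmed" (G), "suspected" (V) or absent
are includable; "excluded" (A) and "status post" (Z) never trigger a match.

* **ACS** — ED diagnosis groups I20, I21, R07 (excluding the full code
  R07.0, pain localized to the throat) or the full code R57.0 (cardiogenic
  shock; other R57 shock subcodes are not cardiac and are matched only as
  the 4-character code).  Attendances *without any ED diagnosis* also count
  via chief complaints 001 (cardiac arrest), 003/004 (chest pain) — but
  only under dispositions compatible with a severe event (inpatient
  admission, death, "other", or missing), which removes cases discharged
  home.
* **MI** — ED diagnosis group I21 only; no chief complaint is specific
  enough for MI, so there is no complaint branch.
* **STR** — ED diagnosis groups I60, I61, I63, I64; complaint branch only
  for CEDIS-PCL 409 (extremity weakness / CVA symptoms), under the same
  severe dispositions.

Two readings of the complaint branch were genuinely open and are exposed as
rule fields rather than hard-coded:

* `complaint_requires_no_dx` (default true): the complaint branch applies
  only to attendances with *no* coded ED diagnosis, so an attendance whose
  only diagnosis is non-matching cannot enter via complaint.
* `complaint_dx_scope` (default `"any"`): an attendance whose only
  diagnoses carry certainty "excluded"/"status post" still counts as
  *having* diagnoses.  Setting `"includable"` treats it as diagnosis-free.

Disposition gating applies only to the complaint branch, not the diagnosis
branch.  Sex and triage play no role in classification; they are
descriptive strata only.  The diagnosis list is treated as an unordered
set.  Rules serialize to YAML so deployed definitions stay auditable.

## Synthetic cohort generator

One attendance is generated as follows.

1. **Volume.** Daily attendance counts are Poisson with mean
   `n_eds × daily_rate_per_ed × w(dow) × dip(t)`, where
   `w(dow) = 1 + a·cos(2π·dow/7)` is a day-of-week factor with amplitude
   `a` (the seven factors average exactly 1) and `dip(t)` is a
   multiplicative drop `m ∈ (0,1]` inside a configurable window, emulating
   the spring-2020 pandemic-onset fall in attendance.
2. **Demographics.** Age band × sex drawn from a joint probability table.
3. **Latent case status.** Adults (age ≥ 20) draw one mutually exclusive
   latent state from {none, ACS-only, MI, STR} with the configured
   prevalences (MI ⊂ ACS by construction); under-20 attendances are
   structural non-cases.  Exclusivity — rather than independent indicator
   draws — is a deliberate design choice: at a single acute visit the
   three conditions are clinically and coding-wise mutually exclusive, and
   exclusivity is what makes the closed-form operating characteristics
   below exact (independent draws would couple the indicators through the
   single chief-complaint field and the "no ED diagnosis" requirement of
   the complaint branch).
4. **Documentation.** A true case receives, with probability
   `p_specific_dx`, a rule-matching ED diagnosis (certainty drawn from
   {confirmed, suspected, missing}); with probability `p_complaint_only`,
   only a rule-matching chief complaint and *no coded diagnosis at all*;
   otherwise unspecific documentation.  A non-case draws at most one false
   signal: a rule-matching diagnosis (`p_false_dx`, certainty from a
   5-level noise distribution that includes excluded/status-post) or a
   rule-matching complaint with no diagnosis (`p_false_complaint`).
   Attendances not designated complaint-only may additionally carry an
   irrelevant noise diagnosis (the pool deliberately contains R07.0 and
   G45.9, which exercise the exclusion and gold-set boundaries).  The
   "complaint-only means no coded diagnosis" convention is what lets the
   complaint branch fire at all under `complaint_requires_no_dx`.
5. **Hospitalization and disposition.** Cases are hospitalized with
   `p_hosp_case` (per indicator, optionally multiplied by an age-band×sex
   modifier), non-cases with `p_hosp_noncase`.  Hospitalized attendances
   get disposition "inpatient admission"; others draw from a configurable
   distribution over home/transfer/other/death/missing.  Field masking
   (triage, disposition, certainty, chief complaint) is applied last.
6. **Discharge records.** Every hospitalized attendance emits an inpatient
   record: a true case always carries its indicator's gold-standard
   discharge group (as main diagnosis, possibly with a non-gold secondary
   code); a non-case never carries a gold group.  The latent truth
   therefore *is* the reference-standard label among linked cases, making
   the reference standard exact in simulation.  The yearly
   hospital-statistics table aggregates the emitted gold codes by year ×
   20-year band × binary sex (attendances with other/missing sex are not
   representable in that table and are omitted from it).

### Closed-form operating characteristics

Among linked (hospitalized) attendances the recorded disposition is always
includable for the complaint branch (inpatient admission, or masked to
missing), so with `c = 1 − P(complaint masked)`:

* sens(MI) = `p_specific_dx` (no complaint branch);
* sens(STR) = `p_specific_dx + p_complaint_only·c`;
* sens(ACS) = prevalence-and-hospitalization-weighted mix of the MI-latent
  and ACS-only-latent branches (an I21 diagnosis and chest-pain complaints
  both satisfy the ACS rule);
* 1 − spec = FP mass over gold-negative mass, where only adult latent-none
  attendances can be false positives:
  `FP = p_false_dx_eff · P(noise certainty includable) + p_false_complaint·c`,
  with `p_false_dx_eff(ACS) = p_false_dx(ACS) + p_false_dx(MI)` because an
  I21 noise diagnosis fires the ACS rule too.  The gold-negative mass adds
  under-20 attendances and the hospitalized cases of the other latent
  states, which by construction never carry this indicator's codes.

Analogous formulas give the expected rule-positive share of all
attendances, the linked fraction, the positive predictive value (equal to
the expected share of the top discharge group among rule positives), and
the expected ED vs hospital-statistics stratum shares and ratios
(`expected_stratum_shares`), which account for stratum-specific
hospitalization modifiers.

### Default configuration

The defaults describe the study conditions the package emulates: 9 EDs,
2019-01-01 to 2021-03-05, 98.5 attendances/ED/day (≈ 700k attendances),
an 11% under-20 share with the attendance load concentrated at 60–79
years, 52.5/47.1/0.4% male/female/other, triage missing 13.6%, and a
spring-2020 dip with multiplier 0.65.  Indicator parameters (prevalence
1.6/0.8/2.6% among adults for ACS/MI/STR; documentation probabilities
0.75+0.15, 0.57+0.25, 0.66+0.15; false-signal rates 4.0/0.4/1.8%;
hospitalization 0.85–0.92 for cases, 0.40 for non-cases) were derived once
from the published margins of that study design — observed ED shares of
4.3/0.6/3.2%, sensitivities ≈ 85/57/80%, specificities ≈ 95/99.6/97.5%, a
43.3% linked fraction, and the gold prevalences those values imply — and
are not tuned thereafter.  With them the closed forms give ED shares of
4.6/0.7/3.3%, sensitivities 84.8/57.0/80.3%, specificities
96.2/99.7/98.2%, and a 41.9% linked fraction.

### What the generator does not emulate

Prevalence, documentation quality and hospitalization do not vary by age,
sex, ED or season (only attendance *volume* does); there are no repeat
visits, no between-ED coding-style differences, no correlation between
triage and case status, and sex plays no role in case risk.  Passing
recovery tests therefore demonstrate that the pipeline's estimators are
correct and calibrated under the assumed data-generating process — not
that the shipped definitions would achieve these operating characteristics
on real registry data, which is exactly why the original validation
against real discharge data cannot be replaced by simulation.

## Statistical choices

* **Exact Clopper–Pearson intervals** (beta-quantile form, via
  `scipy.stats.beta`) for sensitivity/specificity/accuracy; exact
  intervals are the convention of the epidemiological toolchain for
  diagnostic metrics and are conservative (coverage ≥ nominal).  A zero
  denominator raises an explicit `UndefinedMetricError`, never a silent
  NaN.
* **Gold standard scope**: any discharge diagnosis by default;
  `main_only` is available.  Discharge certainty qualifiers do not filter
  the gold standard.
* **Relative numbers for the external comparison** are each stratum's
  share of that source's total cases for the indicator.  This
  distribution-style reading is a documented assumption: the two sources
  have incomparable absolute denominators (a handful of sentinel EDs vs
  all German hospitals), so only distributional congruence is measurable.
  The 0–19 band is excluded (structurally zero ED share); ED denominators
  are complete-case (missing sex dropped from numerator and denominator)
  and restricted to full calendar years.
* **Katz log-scale interval** for share ratios,
  `exp(ln R ± 1.96·√((1−p₁)/(n₁p₁) + (1−p₂)/(n₂p₂)))`; simulation places
  its coverage at ≈ 95% for stratum sizes ≥ 500.  A zero hospital share
  makes the ratio undefined (flagged, not fatal); a zero ED share returns
  ratio 0 with a one-sided interval.
* **Time series**: daily counts with explicit zeros over the full study
  period; 7-day *trailing* moving average (a centered window would need
  future data in a real-time system; the window is configurable), with the
  first six points undefined.  Rolling sensitivity/specificity use
  calendar months — fine enough to see drift, coarse enough for stable
  denominators.
* **Percentages** in descriptive outputs round to one decimal; counts are
  never rounded, so every percentage is reconstructible.

## Reproducibility and problem sizes

All randomness flows through one `numpy` `Generator` seeded from the
configuration (or an explicit override), and every pipeline artifact is
byte-identical across same-seed reruns.  The test suite scales cohorts to
its purpose: ~22k attendances for cohort-level checks, ~54k for parameter
recovery (comfortably inside 3-standard-error bands), 1,000 cohorts of
~200 linked cases for interval-coverage calibration, and ~260k for the
stratum-ratio divergence check; the acceptance script runs the full
study-scale default (~700k).

## Known limitations

* The rule evaluator is O(attendances × diagnoses) pure Python; at the
  study scale (~700k attendances) classification takes a few seconds,
  which is adequate for daily surveillance batches but not tuned further.
* `expected_stratum_shares` assumes prevalence constant across adult
  strata (matching the generator); it would need stratum-resolved
  prevalences if the generator ever gained them.
* The hospital-statistics table covers binary sex only, mirroring the
  published national statistic; other/missing sex is therefore invisible
  to external validation.
* No plotting is included; report CSVs are designed to be chartable
  directly with pandas/matplotlib.
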