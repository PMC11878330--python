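# edsynd

Syndromic surveillance of **acute coronary syndrome (ACS)**, **myocardial
infarction (MI)** and **stroke (STR)** from emergency-department (ED)
routine data: declarative rule-based case definitions over ICD-10-GM
diagnoses and CEDIS-PCL chief complaints, a seeded synthetic cohort
generator with closed-form operating-characteristic oracles, internal
validation against linked hospital discharge diagnoses, and external
validation against yearly aggregated hospital diagnosis statistics.

The package is aimed at public-health epidemiologists and surveillance
engineers who need to *define*, *audit* and *validate* non-communicable
disease indicators on case-based ED data (German NoKeDa-style extracts:
5-year age bands, sex, triage urgency, chief complaint, ED diagnoses with
certainty qualifiers, disposition).

## The method

A syndrome definition labels an attendance a case iff

```
age_band ≥ 20  AND  [ any ED diagnosis with group ∈ G \ exclusions and
                      certainty ∈ {confirmed, suspected, none}
                      OR (no ED diagnosis AND chief complaint ∈ C
                          AND disposition ∈ {inpatient, death, other, missing}) ]
```

with, per indicator: ACS `G = {I20, I21, R07 ∖ R07.0, R57.0}`,
`C = {001, 003, 004}`; MI `G = {I21}`, no complaint branch; STR
`G = {I60, I61, I63, I64}`, `C = {409}`.

*Internal validation* links attendances to inpatient records by attendance
id and uses the discharge diagnosis as reference standard (ACS: I20/I21,
MI: I21, STR: I60/I61/I63/I64).  Sensitivity `tp/(tp+fn)`, specificity
`tn/(tn+fp)` and accuracy get exact 95% Clopper–Pearson intervals from
beta quantiles.  *External validation* compares each (20-year age band ×
sex) stratum's share of ED cases with its share of the national hospital
diagnosis counts via ratios `R = p₁/p₂` with Katz log-scale intervals
`exp(ln R ± 1.96·√((1−p₁)/(n₁p₁) + (1−p₂)/(n₂p₂)))`.

Because real registry extracts are not redistributable, a generator
(`edsynd.simulate`) draws cohorts whose latent case status realizes the
gold standard exactly, and exposes the analytic sensitivity/specificity/
share formulas (`expected_metrics`, `expected_stratum_shares`) that
estimates must recover.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

`examples/03_internal_validation.py` draws a one-year, three-ED cohort
(~108k attendances), classifies it, links it and validates internally:

```
linked 45307 of 108089 attendances (41.9%)

ACS: sensitivity 86.3% (95% CI 84.3-88.1; expected 84.8)
     specificity 96.0% (95% CI 95.9-96.2; expected 96.2)
MI: sensitivity 59.4% (95% CI 55.6-63.1; expected 57.0)
     specificity 99.7% (95% CI 99.7-99.8; expected 99.7)
STR: sensitivity 79.4% (95% CI 77.7-81.0; expected 80.2)
     specificity 98.3% (95% CI 98.2-98.4; expected 98.2)

top discharge groups among ED-identified MI cases:
icd_group  count  proportion
      I21    401    0.766730
      ...
```

Each "expected" value is the closed-form operating characteristic implied
by the generator configuration; the estimates bracket it within their
exact confidence intervals.  The I21 proportion among ED-identified MI
cases is the rule's positive predictive value: the share of ED MI cases
that end with an MI discharge diagnosis.

The other examples cover cohort generation (`01`), classification and the
descriptive baseline table (`02`), the external share-ratio comparison
including a deliberately divergent stratum (`04`), and the full report
pipeline with its manifest (`05`).  A thin CLI mirrors the library:

```bash
edsynd simulate --seed 17 --out data/
edsynd classify --ed data/ed.csv --out labels.csv
edsynd run --seed 17 --out report/
```

## Layout

```
src/edsynd/
  codes.py          ICD-10-GM normalization and group matching
  records.py        domain records (attendance, inpatient, linkage, stats table)
  io.py             CSV readers/writers, lenient enum parsing
  rules.py          SyndromeRule, shipped definitions, evaluator
  simulate.py       cohort generator + closed-form oracles
  internal.py       gold standard, exact-CI metrics, series, rolling metrics
  external.py       stratum shares, Katz ratio intervals
  describe.py       baseline table
  reference_data.py published baseline counts (worked-example input)
  pipeline.py       orchestration + manifest
  cli.py            thin click CLI
```
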