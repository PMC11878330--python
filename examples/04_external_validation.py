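"""External validation: compare the ED cases' age/sex distribution with the
yearly aggregated hospital diagnosis statistics via share ratios.

A ratio near 1 in a stratum means that stratum holds the same share of ED
cases as of nationally coded hospital diagnoses.  Here the generator is
given lowered hospitalization for young women with cardiac events, which
inflates their ED share relative to the hospital statistics.
"""

import dataclasses
from datetime import date

import edsynd as e

cfg = dataclasses.replace(
    e.default_config(seed=4), n_eds=3, daily_rate_per_ed=120.0,
    period=(date(2019, 1, 1), date(2020, 12, 31)),
    hosp_rate_modifiers={("20-39", "female"): 0.25},
)
bundle = e.generate_cohort(cfg)
labels = e.classify_cohort(bundle.attendances)
by_id = {a.attendance_id: a for a in bundle.attendances}
pos = [by_id[i] for i in labels.index[labels["acs"]]]

ratios = e.external_ratios(pos, bundle.hospital_stats, "ACS", (2019, 2020))
print("ACS: ED share vs hospital-statistics share by stratum")
print(ratios.round(3).to_string(index=False))
print()
expected = e.expected_stratum_shares(cfg, "ACS").set_index(["age_band", "sex"])
print(f"analytic ratio for women 20-39: "
      f"{expected.loc[('20-39', 'female'), 'ratio']:.2f}")
print("Strata with ratios near 1 are congruent with the national statistics;")
print("the elevated young-female ratio reflects the configured divergence in")
print("hospitalization behavior, the pattern external validation is built to expose.")
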