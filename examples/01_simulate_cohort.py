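"""Draw a small synthetic ED cohort and look at its structure.

The generator emulates a multi-ED German surveillance extract: Poisson
daily attendance with weekly seasonality and a spring-2020 dip, latent
ACS/MI/stroke case status, imperfect ED coding, and inpatient discharge
records for hospitalized attendances.
"""

import dataclasses
from datetime import date

import edsynd as e

cfg = dataclasses.replace(
    e.default_config(seed=1),
    n_eds=2,
    daily_rate_per_ed=50.0,
    period=(date(2020, 1, 1), date(2020, 6, 30)),
)
bundle = e.generate_cohort(cfg)

print(f"attendances:        {len(bundle.attendances)}")
print(f"inpatient records:  {len(bundle.inpatient)} "
      f"({100 * len(bundle.inpatient) / len(bundle.attendances):.1f}% hospitalized)")
print(f"true cases:         " + ", ".join(
    f"{k.upper()} {int(bundle.truth[k].sum())}" for k in ("acs", "mi", "str")))
print(f"hospital-stats rows: {len(bundle.hospital_stats)} "
      "(year x ICD group x age band x sex)")
print()
a = bundle.attendances[0]
print("first attendance:", a.attendance_id, a.admission_date, a.sex.value,
      f"age {a.age_group_lower}-{a.age_group_lower + 4}",
      "dx", [f"{d.code.raw}:{d.certainty.value}" for d in a.diagnoses])
print()
print("The hospitalized fraction is what internal validation can link;")
print("true-case counts are the latent gold standard the pipeline recovers.")
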