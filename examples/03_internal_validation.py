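"""Internal validation: link ED attendances to discharge diagnoses and
estimate rule accuracy against that reference standard.

Sensitivity = P(rule positive | gold-standard discharge code present),
specificity = P(rule negative | absent), both with exact 95%
Clopper-Pearson intervals.  The closed-form generator expectation is
printed next to each estimate.
"""

import dataclasses
from datetime import date

import edsynd as e

cfg = dataclasses.replace(
    e.default_config(seed=3), n_eds=3, daily_rate_per_ed=100.0,
    period=(date(2019, 1, 1), date(2019, 12, 31)),
    trend=dataclasses.replace(e.default_config().trend,
                              dip_start=date(2019, 3, 1), dip_end=date(2019, 3, 14)),
)
bundle = e.generate_cohort(cfg)
labels = e.classify_cohort(bundle.attendances)
linked = e.link_cases(bundle.attendances, bundle.inpatient)
gold = e.gold_labels(linked)

print(f"linked {len(linked)} of {len(bundle.attendances)} attendances "
      f"({100 * len(linked) / len(bundle.attendances):.1f}%)\n")
for ind in ("ACS", "MI", "STR"):
    lab = labels.loc[gold.index, ind.lower()]
    cm = e.confusion(lab, gold[ind.lower()])
    sens = e.metric_with_ci(cm, "sensitivity")
    spec = e.metric_with_ci(cm, "specificity")
    exp_sens, exp_spec = e.expected_metrics(cfg, ind)
    print(f"{ind}: sensitivity {100 * sens.value:.1f}% "
          f"(95% CI {100 * sens.ci_low:.1f}-{100 * sens.ci_high:.1f}; expected {100 * exp_sens:.1f})")
    print(f"     specificity {100 * spec.value:.1f}% "
          f"(95% CI {100 * spec.ci_low:.1f}-{100 * spec.ci_high:.1f}; expected {100 * exp_spec:.1f})")

mi_lab = labels.loc[gold.index, "mi"]
mi_pos = [c for c in linked if bool(mi_lab[c.attendance.attendance_id])]
print("\ntop discharge groups among ED-identified MI cases:")
print(e.top_discharge_groups(mi_pos, k=5).to_string(index=False))
print("\nA high I21 share means ED-identified MI cases mostly end with an MI")
print("discharge diagnosis; the remainder are the rule's false positives.")
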