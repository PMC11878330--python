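"""Declarative syndrome definitions and their evaluator.

A syndrome definition labels an ED attendance as a case of an indicator
(acute coronary syndrome, myocardial infarction, stroke) from the routinely
documented fields alone.  Each rule combines:

* a diagnosis branch — any ED diagnosis whose ICD-10-GM group is in
  ``dx_groups`` (minus full-code ``dx_exclusions``, plus full-code
  ``dx_code_inclusions``) and whose certainty qualifier is includable
  (confirmed, suspected, or no qualifier; "excluded"/"status post" never
  trigger a match);
* an optional chief-complaint branch — for attendances *without any ED
  diagnosis*, a CEDIS-PCL chief complaint in ``complaint_codes`` counts as a
  case only under dispositions that are compatible with a severe acute event
  (inpatient admission, death, "other", or missing disposition), which
  screens out cases discharged home;
* an age gate — the 5-year age-band lower bound must be at least
  ``min_age_lower_bound`` (20 years for all shipped rules, since acute
  coronary events and strokes are rare below that and age is only available
  in 5-year bands).

Rules are data: they serialize to YAML so deployed definitions stay
auditable and versioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .codes import icd_in_group
from .records import Certainty, Disposition, EDAttendance

__all__ = ["SyndromeRule", "builtin_rules", "classify", "classify_cohort", "INDICATORS"]

INDICATORS = ("ACS", "MI", "STR")

#: certainty qualifiers under which a diagnosis can trigger a rule
INCLUDABLE_CERTAINTIES = frozenset(
    {Certainty.CONFIRMED, Certainty.SUSPECTED, Certainty.MISSING}
)

#: dispositions under which a complaint-only presentation still counts
SEVERE_DISPOSITIONS = frozenset(
    {
        Disposition.INPATIENT_ADMISSION,
        Disposition.DEATH,
        Disposition.OTHER,
        Disposition.MISSING,
    }
)


@dataclass(frozen=True)
class SyndromeRule:
    """A declarative rule-based case definition.

    ``complaint_requires_no_dx`` implements the reading that the complaint
    branch applies only to attendances *without an ED diagnosis*: any
    documented diagnosis — regardless of certainty — blocks the branch.  Set
    ``complaint_dx_scope="includable"`` to let diagnoses with only
    excluded/status-post certainty count as "no diagnosis" instead.
    """

    name: str
    dx_groups: frozenset[str]
    dx_exclusions: frozenset[str] = frozenset()
    dx_code_inclusions: frozenset[str] = frozenset()
    dx_certainties: frozenset[Certainty] = INCLUDABLE_CERTAINTIES
    complaint_codes: frozenset[str] = frozenset()
    complaint_dispositions: frozenset[Disposition] = SEVERE_DISPOSITIONS
    min_age_lower_bound: int = 20
    complaint_requires_no_dx: bool = True
    complaint_dx_scope: str = "any"  # "any" | "includable"

    def __post_init__(self) -> None:
        if not self.dx_groups and not self.dx_code_inclusions:
            raise ValueError(f"rule {self.name}: no diagnosis codes configured")
        if self.min_age_lower_bound < 0 or self.min_age_lower_bound % 5:
            raise ValueError(
                f"rule {self.name}: min_age_lower_bound must be a multiple of 5"
            )
        if self.complaint_dx_scope not in ("any", "includable"):
            raise ValueError(f"rule {self.name}: bad complaint_dx_scope")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["dx_groups"] = sorted(self.dx_groups)
        d["dx_exclusions"] = sorted(self.dx_exclusions)
        d["dx_code_inclusions"] = sorted(self.dx_code_inclusions)
        d["dx_certainties"] = sorted(c.value for c in self.dx_certainties)
        d["complaint_codes"] = sorted(self.complaint_codes)
        d["complaint_dispositions"] = sorted(d.value for d in self.complaint_dispositions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyndromeRule":
        return cls(
            name=d["name"],
            dx_groups=frozenset(d.get("dx_groups", ())),
            dx_exclusions=frozenset(d.get("dx_exclusions", ())),
            dx_code_inclusions=frozenset(d.get("dx_code_inclusions", ())),
            dx_certainties=frozenset(
                Certainty(c) for c in d.get("dx_certainties", [c.value for c in INCLUDABLE_CERTAINTIES])
            ),
            complaint_codes=frozenset(d.get("complaint_codes", ())),
            complaint_dispositions=frozenset(
                Disposition(x)
                for x in d.get("complaint_dispositions", [x.value for x in SEVERE_DISPOSITIONS])
            ),
            min_age_lower_bound=int(d.get("min_age_lower_bound", 20)),
            complaint_requires_no_dx=bool(d.get("complaint_requires_no_dx", True)),
            complaint_dx_scope=d.get("complaint_dx_scope", "any"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyndromeRule":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- matching helpers --------------------------------------------------
    def dx_matches(self, code, certainty: Certainty) -> bool:
        """Does one diagnosis (code + certainty) trigger the diagnosis branch?"""
        if certainty not in self.dx_certainties:
            return False
        if icd_in_group(code, self.dx_groups, self.dx_exclusions):
            return True
        return any(code.raw.startswith(incl) for incl in self.dx_code_inclusions)


def builtin_rules() -> dict[str, SyndromeRule]:
    """The three shipped syndrome definitions.

    ACS
        ED diagnoses I20 (angina), I21 (MI), R07 excluding R07.0
        (throat/chest pain, but not pain localized to the throat) or the
        full code R57.0 (cardiogenic shock; other R57 shock subcodes are not
        cardiac and do not count).  Complaint branch: CEDIS-PCL 001 cardiac
        arrest, 003 chest pain (cardiac features), 004 chest pain
        (non-cardiac features), under severe dispositions only.
    MI
        ED diagnosis group I21 only; no complaint is specific enough, so no
        complaint branch.
    STR
        ED diagnoses I60 (subarachnoid hemorrhage), I61 (intracerebral
        hemorrhage), I63 (cerebral infarction), I64 (stroke unspecified).
        Complaint branch: only CEDIS-PCL 409 (extremity weakness / symptoms
        of CVA), under severe dispositions.

    All three require age band >= 20 years and accept certainty confirmed,
    suspected, or missing.
    """
    acs = SyndromeRule(
        name="ACS",
        dx_groups=frozenset({"I20", "I21", "R07"}),
        dx_exclusions=frozenset({"R07.0"}),
        dx_code_inclusions=frozenset({"R57.0"}),
        complaint_codes=frozenset({"001", "003", "004"}),
    )
    mi = SyndromeRule(
        name="MI",
        dx_groups=frozenset({"I21"}),
        complaint_codes=frozenset(),
    )
    stroke = SyndromeRule(
        name="STR",
        dx_groups=frozenset({"I60", "I61", "I63", "I64"}),
        complaint_codes=frozenset({"409"}),
    )
    return {"ACS": acs, "MI": mi, "STR": stroke}


def classify(att: EDAttendance, rule: SyndromeRule) -> bool:
    """Evaluate one syndrome rule on one attendance."""
    if att.age_group_lower < rule.min_age_lower_bound:
        return False
    # diagnosis branch
    for dx in att.diagnoses:
        if rule.dx_matches(dx.code, dx.certainty):
            return True
    # complaint branch
    if not rule.complaint_codes or att.chief_complaint not in rule.complaint_codes:
        return False
    if rule.complaint_requires_no_dx:
        if rule.complaint_dx_scope == "any":
            blocking = att.diagnoses
        else:
            blocking = [
                d for d in att.diagnoses if d.certainty in rule.dx_certainties
            ]
        if blocking:
            return False
    return att.disposition in rule.complaint_dispositions


def classify_cohort(
    atts: Sequence[EDAttendance],
    rules: Mapping[str, SyndromeRule] | None = None,
) -> pd.DataFrame:
    """Label every attendance with every rule.

    Returns a DataFrame indexed by ``attendance_id`` with one boolean column
    per rule (column names lowercased).
    """
    if rules is None:
        rules = builtin_rules()
    ids = [a.attendance_id for a in atts]
    if len(set(ids)) != len(ids):
        raise ValueError("attendance ids are not unique")
    data = {
        name.lower(): [classify(a, rule) for a in atts]
        for name, rule in rules.items()
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="attendance_id"))
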