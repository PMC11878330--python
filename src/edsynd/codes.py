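"""ICD-10-GM code handling.

German emergency-department and hospital-billing data carry diagnoses as
ICD-10-GM codes: an uppercase letter, two digits, and an optional subcode
after a dot (e.g. ``I21.0``).  Syndrome definitions and gold standards in
this package operate on the three-character *group* (``I21``), with
occasional full-code exclusions (``R07.0``) or inclusions (``R57.0``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = ["ICDCode", "normalize_icd", "icd_in_group"]

# letter + two digits, optionally followed by "." and alphanumeric subcode
# (ICD-10-GM also uses suffixes like "!" and "+"; they are tolerated and kept
# in ``raw`` but play no role in group matching)
_ICD_RE = re.compile(r"^[A-Z][0-9]{2}([.\-][0-9A-Z]{0,4})?[!+*]?$")


@dataclass(frozen=True, slots=True)
class ICDCode:
    """A normalized ICD-10-GM code.

    Attributes
    ----------
    raw
        The full documented code, uppercased and stripped (``"I21.0"``).
    group
        The three-character group, letter plus two digits (``"I21"``).
    """

    raw: str
    group: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


def normalize_icd(raw: str) -> ICDCode:
    """Normalize a documented ICD-10-GM code string.

    Uppercases, strips surrounding whitespace, and extracts the
    three-character group from the leading characters.  Subcode digits after
    the dot are preserved in ``raw``.  Normalization is idempotent.

    Raises
    ------
    ValueError
        If the code does not start with a letter followed by two digits.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty ICD code")
    code = str(raw).strip().upper()
    if not _ICD_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {raw!r}")
    return ICDCode(raw=code, group=code[:3])


def icd_in_group(
    code: ICDCode,
    groups: Iterable[str],
    exclusions: Iterable[str] = (),
) -> bool:
    """Group-prefix membership test with full-code exclusions.

    ``True`` iff ``code.group`` is one of ``groups`` and ``code.raw`` is not
    one of the excluded full codes.  Matching is by three-character group
    prefix, so ``I21.0`` matches group ``I21``; the exclusion list names full
    codes such as ``R07.0``.
    """
    return code.group in set(groups) and code.raw not in set(exclusions)
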