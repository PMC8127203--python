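"""Deterministic juvenile arthritis case definition for claim-level data.

The validated rule: an individual is a JA case if, before the 16th birthday,
they have one or more hospitalizations with a relevant diagnosis (ever), or
two or more physician visits with a relevant diagnosis at least eight weeks
apart but no more than two years apart. Relevant diagnoses are rheumatoid
arthritis and ankylosing spondylitis codes (ICD-9-CM 714, 720; ICD-10-CA
M05, M06, M08, M45) — a narrower set than the JA-related *contact* codes
used by the model-based utilization measure.

Restricted-window variants (birth to age 2; ages 14 to 16) emulate settings
where administrative data cover only a short period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .grid import DAYS_PER_YEAR, MAX_DAY
from .simdata import ClaimRecord

DEFINITION_ICD9 = ("714", "720")
DEFINITION_ICD10 = ("M05", "M06", "M08", "M45")


@dataclass(frozen=True)
class CaseDefinitionRule:
    icd9_roots: tuple[str, ...] = DEFINITION_ICD9
    icd10_roots: tuple[str, ...] = DEFINITION_ICD10
    min_visits: int = 2
    min_gap_days: int = 56  # "at least eight weeks apart", inclusive
    max_gap_days: int = 730  # "no more than two years apart", inclusive
    window: tuple[int, int] = (0, MAX_DAY)  # [lo, hi) in days since birth

    def __post_init__(self):
        if self.min_gap_days > self.max_gap_days:
            raise ValueError("min_gap_days must not exceed max_gap_days")
        lo, hi = self.window
        if not (0 <= lo < hi <= MAX_DAY):
            raise ValueError(f"window must lie within [0, {MAX_DAY}]")
        if self.min_visits != 2:
            raise ValueError("only the published two-visit rule is implemented")

    def in_window(self, day: int) -> bool:
        return self.window[0] <= day < self.window[1]

    def matches(self, code: str, icd_version: int) -> bool:
        """Prefix match of the code's category against the definition set."""
        root = str(code).strip().upper()[:3]
        if icd_version == 9:
            return root in self.icd9_roots
        if icd_version == 10:
            return root in self.icd10_roots
        raise ValueError(f"icd_version must be 9 or 10, got {icd_version!r}")


def qualifying_pair_exists(visit_days: list[int], rule: CaseDefinitionRule) -> bool:
    """True iff some pair of visit days is min_gap..max_gap days apart.

    The input must be sorted ascending (checked); the scan is then linear:
    for each later visit only the earliest visit within max_gap needs
    checking, since it realizes the largest admissible gap.
    """
    days = list(visit_days)
    for a, b in zip(days, days[1:]):
        if b < a:
            raise ValueError("visit_days must be sorted ascending")
    i = 0
    for k in range(1, len(days)):
        while days[k] - days[i] > rule.max_gap_days:
            i += 1
        if i < k and days[k] - days[i] >= rule.min_gap_days:
            return True
    return False


def classify_deterministic(
    claims: list[ClaimRecord], rule: CaseDefinitionRule = CaseDefinitionRule()
) -> str:
    """Apply the deterministic definition to one person's claims."""
    relevant_visit_days = set()
    for c in claims:
        if not rule.in_window(c.day):
            continue
        coded = any(rule.matches(code, c.icd_version) for code in c.diagnosis_codes)
        if not coded:
            continue
        if c.record_type == "hospital":
            if not c.newborn_flag:
                return "case"
        else:
            relevant_visit_days.add(c.day)
    if qualifying_pair_exists(sorted(relevant_visit_days), rule):
        return "case"
    return "control"


def windowed_rules() -> list[CaseDefinitionRule]:
    """Full-window rule plus the two restricted-window sensitivity rules."""
    full = CaseDefinitionRule()
    first_two_years = replace(full, window=(0, math.ceil(2 * DAYS_PER_YEAR)))
    last_two_years = replace(full, window=(math.ceil(14 * DAYS_PER_YEAR), MAX_DAY))
    return [full, first_two_years, last_two_years]
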