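"""New-user cohort construction with inclusion/exclusion rules and follow-up.

Cohort entry (the index date) is the patient's first-ever antipsychotic
claim, and it must fall inside the accrual window; a patient whose first-ever
claim precedes the window is not a new user within the window and is logged
as ``prior_use``. Remaining exclusions, applied in order so each excluded
candidate carries exactly one reason: no dementia, age under the minimum at
entry, any antipsychotic claim during the washout year before entry, and no
subsequent antipsychotic claim in the 12 months after entry. Follow-up runs
from entry to death or 12 months, whichever comes first.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd

from .model import (
    ContractError,
    DataIntegrityError,
    Patient,
    PrescriptionClaim,
    StudyConfig,
    completed_years,
)

__all__ = ["CohortMember", "ExclusionLog", "find_index", "build_cohort", "active_at"]

EXCLUSION_ORDER = ("no_dementia", "under_age", "prior_use", "no_subsequent_rx")
RETAINED = "retained"


@dataclass
class CohortMember:
    patient_id: str
    index_date: dt.date
    followup_end: dt.date
    exit_reason: str  # "end_of_study" | "death"


class ExclusionLog:
    """Per-candidate disposition: the first-triggering exclusion reason, or retained."""

    def __init__(self):
        self.entries: List[tuple] = []  # (patient_id, reason)

    def add(self, patient_id: str, reason: str) -> None:
        self.entries.append((patient_id, reason))

    def counts(self) -> Dict[str, int]:
        out = {r: 0 for r in EXCLUSION_ORDER + (RETAINED,)}
        for _, r in self.entries:
            out[r] += 1
        return out

    def reason(self, patient_id: str) -> Optional[str]:
        for pid, r in self.entries:
            if pid == patient_id:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["patient_id", "reason"])


def find_index(claims: Sequence[PrescriptionClaim], config: StudyConfig) -> Optional[dt.date]:
    """Index date: the first-ever claim's dispense date, if inside accrual.

    Returns None when the patient has no claims or their first-ever claim
    falls outside the accrual window (such a patient is not a new user
    within the window, even if later claims fall inside it).
    """
    if not claims:
        return None
    first = min(c.dispense_date for c in claims)
    if config.accrual_start <= first <= config.accrual_end:
        return first
    return None


def build_cohort(
    patients: Iterable[Patient],
    claims: Iterable[PrescriptionClaim],
    config: StudyConfig,
) -> tuple:
    """Apply all inclusion/exclusion rules; returns (members, exclusion log).

    Candidates are patients with at least one claim inside the accrual
    window. Cohort logic uses dates only, so cleaned and raw claims give
    identical cohorts.
    """
    pat = {p.patient_id: p for p in patients}
    by_patient: Dict[str, list] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    orphans = sorted(set(by_patient) - set(pat))
    if orphans:
        raise DataIntegrityError(
            f"claims reference patient(s) absent from the patient table: {', '.join(orphans[:5])}"
        )

    members, log = [], ExclusionLog()
    for pid in sorted(by_patient):
        cl = by_patient[pid]
        p = pat[pid]
        dates = sorted(c.dispense_date for c in cl)
        in_window = [d for d in dates if config.accrual_start <= d <= config.accrual_end]
        if not in_window:
            continue  # never a candidate
        index = find_index(cl, config)
        entry_ref = index if index is not None else in_window[0]

        reason = None
        if not p.dementia:
            reason = "no_dementia"
        elif completed_years(p.birth_date, entry_ref) < config.min_age_years:
            reason = "under_age"
        elif index is None or any(
            d < index and (index - d).days <= config.washout_days for d in dates
        ):
            reason = "prior_use"
        elif not any(
            index < d <= index + dt.timedelta(days=config.followup_days) for d in dates
        ):
            reason = "no_subsequent_rx"

        if reason is not None:
            log.add(pid, reason)
            continue
        end = index + dt.timedelta(days=config.followup_days)
        exit_reason = "end_of_study"
        if p.death_date is not None and p.death_date < end:
            end, exit_reason = p.death_date, "death"
        members.append(CohortMember(pid, index, end, exit_reason))
        log.add(pid, RETAINED)
    return members, log


def active_at(
    member: CohortMember,
    claims: Sequence[PrescriptionClaim],
    timepoint_days: int,
    config: StudyConfig,
    use_cleaned: bool = True,
) -> bool:
    """True iff follow-up reaches the timepoint and some eligible claim covers it."""
    from .exposure import eligible_claims  # local import: exposure depends on nothing here

    if timepoint_days not in config.timepoints_days:
        raise ContractError(f"timepoint {timepoint_days} not in configured timepoints")
    target = member.index_date + dt.timedelta(days=timepoint_days)
    if member.followup_end < target:
        return False
    return bool(eligible_claims(claims, member.index_date, timepoint_days, config, use_cleaned))
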