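"""Route-specific cleaning rules for dispensed quantity and day's supply.

Three rule families, dispatched on (route, formulation):

* **oral/rectal** — if the next claim for the same drug is dispensed within
  the refill window (100 days, inclusive), trust the recorded day's supply;
  otherwise conservatively set it to quantity / 5, rounded half-up and floored
  at 1 (5 units per day being the fastest plausible dosing rate).
* **long-acting injectable** — trust the recorded day's supply when it
  exceeds the drug's minimum dosing interval; otherwise use the minimum
  interval, or the actual gap to the next long-acting claim when that gap is
  shorter than the minimum.
* **short-acting injectable** — repair the dispensed quantity from the
  billable cost per mL and total billed cost when they disagree with the
  recorded quantity by more than a relative tolerance, then apply the
  oral day's-supply rule using the repaired quantity.

Rules mutate only the ``cleaned_*`` fields; a modified flag is set exactly
when the cleaned value differs from the raw value, which makes ``clean_all``
idempotent. Every rule evaluation is logged in a :class:`CleaningReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from .model import (
    ConfigError,
    ContractError,
    DosingIntervalTable,
    Formulation,
    PrescriptionClaim,
    Route,
    StudyConfig,
    round_half_up,
)

__all__ = [
    "CleaningRecord",
    "CleaningReport",
    "clean_oral_rectal",
    "clean_long_acting",
    "clean_short_acting_injectable",
    "clean_all",
]

# branch labels
ORAL_KEEP = "oral_keep"
ORAL_FALLBACK = "oral_fallback"
LA_KEEP = "la_keep"
LA_SET_MIN_INTERVAL = "la_set_min_interval"
LA_SET_GAP = "la_set_gap"
SA_QUANTITY_REPAIR = "sa_quantity_repair"
SA_KEEP = "sa_keep"
NONE = "none"


@dataclass
class CleaningRecord:
    """One rule evaluation on one claim field.

    ``branch`` is the branch that fired; ``rule_applied`` equals the branch
    when this run changed the cleaned value and ``none`` otherwise.
    """

    claim_id: str
    patient_id: str
    field: str  # "quantity" or "days_supply"
    branch: str
    rule_applied: str
    value_before: float
    value_after: float

    @property
    def changed(self) -> bool:
        return self.rule_applied != NONE


class CleaningReport:
    """Log of every rule evaluation from one cleaning run."""

    def __init__(self, records: Optional[List[CleaningRecord]] = None):
        self.records: List[CleaningRecord] = list(records or [])

    def extend(self, records: Iterable[CleaningRecord]) -> None:
        self.records.extend(records)

    @property
    def modified_claim_ids(self) -> set:
        return {r.claim_id for r in self.records if r.changed}

    @property
    def n_modifications(self) -> int:
        return sum(1 for r in self.records if r.changed)

    def to_frame(self) -> pd.DataFrame:
        cols = ["claim_id", "patient_id", "field", "branch", "rule_applied",
                "value_before", "value_after"]
        return pd.DataFrame([r.__dict__ for r in self.records], columns=cols)


def _check_sorted(claims: Sequence[PrescriptionClaim]) -> None:
    for a, b in zip(claims, claims[1:]):
        if b.dispense_date < a.dispense_date:
            raise ContractError("claims must be sorted by dispense date")


def _next_same_drug(claims: Sequence[PrescriptionClaim], i: int) -> Optional[PrescriptionClaim]:
    """First claim after position i for the same drug at a strictly later date."""
    c = claims[i]
    for d in claims[i + 1:]:
        if d.drug == c.drug and d.formulation == c.formulation and d.dispense_date > c.dispense_date:
            return d
    return None


def _apply_days(claim: PrescriptionClaim, branch: str, new_days: int) -> CleaningRecord:
    before = claim.cleaned_days_supply
    changed = new_days != before
    if changed:
        claim.cleaned_days_supply = new_days
        claim.days_supply_modified = claim.cleaned_days_supply != claim.days_supply
    return CleaningRecord(
        claim_id=claim.claim_id,
        patient_id=claim.patient_id,
        field="days_supply",
        branch=branch,
        rule_applied=branch if changed else NONE,
        value_before=before,
        value_after=new_days,
    )


def _oral_days_rule(claims: Sequence[PrescriptionClaim], config: StudyConfig) -> list:
    """Shared day's-supply rule for oral/rectal and short-acting injectables."""
    records = []
    for i, c in enumerate(claims):
        nxt = _next_same_drug(claims, i)
        if nxt is not None and (nxt.dispense_date - c.dispense_date).days <= config.next_fill_window_days:
            branch, new_days = ORAL_KEEP, c.cleaned_days_supply
        else:
            branch = ORAL_FALLBACK
            new_days = max(1, round_half_up(c.cleaned_quantity / config.oral_fallback_divisor))
        records.append(_apply_days(c, branch, new_days))
    return records


def clean_oral_rectal(claims: Sequence[PrescriptionClaim], config: StudyConfig) -> list:
    """Clean day's supply for one patient's oral/rectal claims (sorted by date)."""
    for c in claims:
        if c.route not in (Route.ORAL, Route.RECTAL):
            raise ContractError(f"claim {c.claim_id} is not oral/rectal")
    _check_sorted(claims)
    return _oral_days_rule(claims, config)


def clean_long_acting(
    claims: Sequence[PrescriptionClaim],
    intervals: DosingIntervalTable,
    config: StudyConfig,
) -> list:
    """Clean day's supply for one patient's long-acting injectable claims."""
    for c in claims:
        if c.formulation is not Formulation.LONG_ACTING:
            raise ContractError(f"claim {c.claim_id} is not long-acting")
        if c.drug not in intervals:
            raise ConfigError(
                f"no minimum dosing interval configured for long-acting drug '{c.drug}'"
            )
    _check_sorted(claims)
    records = []
    for i, c in enumerate(claims):
        m = intervals.interval(c.drug)
        nxt = None  # next long-acting claim of ANY long-acting drug
        for d in claims[i + 1:]:
            if d.dispense_date > c.dispense_date:
                nxt = d
                break
        if c.cleaned_days_supply > m:
            branch, new_days = LA_KEEP, c.cleaned_days_supply
        elif nxt is None:
            branch, new_days = LA_SET_MIN_INTERVAL, m
        else:
            gap = (nxt.dispense_date - c.dispense_date).days
            if gap < m:
                branch, new_days = LA_SET_GAP, gap
            else:
                branch, new_days = LA_SET_MIN_INTERVAL, m
        records.append(_apply_days(c, branch, new_days))
    return records


def clean_short_acting_injectable(
    claims: Sequence[PrescriptionClaim], config: StudyConfig
) -> list:
    """Repair quantity from costs, then clean day's supply, for short-acting injectables."""
    for c in claims:
        if c.route is not Route.INJECTABLE or c.formulation is not Formulation.IMMEDIATE:
            raise ContractError(f"claim {c.claim_id} is not a short-acting injectable")
    _check_sorted(claims)
    records = []
    for c in claims:
        before = c.cleaned_quantity
        branch, new_q = SA_KEEP, before
        if c.unit_cost is not None and c.total_cost is not None and c.unit_cost > 0 and c.total_cost > 0:
            mismatch = abs(c.cleaned_quantity * c.unit_cost - c.total_cost) / c.total_cost
            if mismatch > config.cost_mismatch_tolerance:
                branch, new_q = SA_QUANTITY_REPAIR, round(c.total_cost / c.unit_cost, 2)
        changed = new_q != before
        if changed:
            c.cleaned_quantity = new_q
            c.quantity_modified = c.cleaned_quantity != c.quantity
        records.append(
            CleaningRecord(
                claim_id=c.claim_id,
                patient_id=c.patient_id,
                field="quantity",
                branch=branch,
                rule_applied=branch if changed else NONE,
                value_before=before,
                value_after=new_q,
            )
        )
    records.extend(_oral_days_rule(claims, config))
    return records


def _family(claim: PrescriptionClaim) -> str:
    if claim.route in (Route.ORAL, Route.RECTAL):
        return "oral"
    if claim.formulation is Formulation.LONG_ACTING:
        return "la"
    return "sa"


def clean_all(
    claims: Iterable[PrescriptionClaim],
    intervals: DosingIntervalTable,
    config: StudyConfig,
) -> tuple:
    """Dispatch every claim to exactly one rule family; returns (claims, report).

    Claims are mutated in place (cleaned fields and flags only). Idempotent:
    a second run reports zero modifications and changes nothing.
    """
    claims = list(claims)
    report = CleaningReport()
    by_patient: dict = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    for pid in sorted(by_patient):
        group = sorted(by_patient[pid], key=lambda c: (c.dispense_date, c.claim_id))
        oral = [c for c in group if _family(c) == "oral"]
        la = [c for c in group if _family(c) == "la"]
        sa = [c for c in group if _family(c) == "sa"]
        if oral:
            report.extend(clean_oral_rectal(oral, config))
        if la:
            report.extend(clean_long_acting(la, intervals, config))
        if sa:
            report.extend(clean_short_acting_injectable(sa, config))
    return claims, report
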