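"""Chlorpromazine-equivalent daily dose computation at follow-up timepoints.

A claim's daily dose is strength x quantity / day's supply (total dispensed
drug mass spread evenly over the supply period), converted to mg of
chlorpromazine per day by the (drug, formulation) potency factor. At
initiation (day 0) only claims dispensed on the index date contribute; at
later timepoints a claim contributes when it was dispensed within the
100-day lookback window ending at the timepoint *and* its day's supply covers
the timepoint under the half-open convention [dispense, dispense + supply).
Eligible contributions are summed over all drugs and routes, once with raw
fields and once with cleaned fields (eligibility re-derived under each), so
the effect of data cleaning on each patient's total is measurable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    ContractError,
    DoseEquivalenceTable,
    Formulation,
    PrescriptionClaim,
    Route,
    RouteClass,
    StudyConfig,
)
from .cohort import CohortMember

__all__ = [
    "ExposureAssessment",
    "UnmappedDrugError",
    "daily_dose_mg",
    "cpz_equivalent_mg",
    "eligible_claims",
    "classify_route",
    "assess",
    "assess_cohort",
]


class UnmappedDrugError(Exception):
    """Raised when claims reference drugs absent from the equivalence table."""

    def __init__(self, drugs):
        self.drugs = sorted(set(drugs))
        super().__init__(
            "no chlorpromazine-equivalence entry for: " + ", ".join(self.drugs)
        )


@dataclass
class ExposureAssessment:
    """Total chlorpromazine-equivalent daily dose for one patient-timepoint."""

    patient_id: str
    timepoint_days: int
    contributing_claim_ids: Tuple[str, ...]
    route_class: RouteClass
    n_drugs: int
    total_cpz_mg_raw: float
    total_cpz_mg_cleaned: float
    modified_by_cleaning: bool


def daily_dose_mg(claim: PrescriptionClaim, use_cleaned: bool = True) -> float:
    """Milligrams of drug per day: strength x quantity / day's supply."""
    if use_cleaned:
        return claim.strength_mg * claim.cleaned_quantity / claim.cleaned_days_supply
    return claim.strength_mg * claim.quantity / claim.days_supply


def cpz_equivalent_mg(
    claim: PrescriptionClaim, table: DoseEquivalenceTable, use_cleaned: bool = True
) -> float:
    """Chlorpromazine-equivalent mg/day for one claim."""
    try:
        factor = table.factor(claim.drug, claim.formulation)
    except KeyError:
        raise UnmappedDrugError([claim.drug]) from None
    return daily_dose_mg(claim, use_cleaned) * factor


def eligible_claims(
    claims: Sequence[PrescriptionClaim],
    index_date: dt.date,
    timepoint_days: int,
    config: StudyConfig,
    use_cleaned: bool = True,
) -> list:
    """Claims contributing exposure at a timepoint.

    Day 0: claims dispensed exactly on the index date. Later timepoints t:
    dispensed within the half-open lookback window (t - lookback, t] and
    covering t under the half-open supply interval [dispense, dispense + ds).
    """
    if timepoint_days < 0:
        raise ContractError("timepoint must be >= 0")
    if timepoint_days == 0:
        return [c for c in claims if c.dispense_date == index_date]
    target = index_date + dt.timedelta(days=timepoint_days)
    window_start = target - dt.timedelta(days=config.lookback_days)  # exclusive
    out = []
    for c in claims:
        if not (window_start < c.dispense_date <= target):
            continue
        ds = c.cleaned_days_supply if use_cleaned else c.days_supply
        if c.dispense_date <= target < c.dispense_date + dt.timedelta(days=ds):
            out.append(c)
    return out


def _category(claim: PrescriptionClaim) -> RouteClass:
    if claim.route in (Route.ORAL, Route.RECTAL):
        return RouteClass.ORAL
    if claim.formulation is Formulation.LONG_ACTING:
        return RouteClass.LONG_ACTING_INJECTABLE
    return RouteClass.REGULAR_INJECTABLE


def classify_route(claims: Sequence[PrescriptionClaim]) -> RouteClass:
    """Single administration-route stratum, or MULTIPLE when routes mix.

    Rectal folds into the oral stratum; injectables split into regular
    (short-acting) and long-acting.
    """
    if not claims:
        raise ContractError("classify_route requires a non-empty claim set")
    cats = {_category(c) for c in claims}
    return cats.pop() if len(cats) == 1 else RouteClass.MULTIPLE


def assess(
    patient_id: str,
    claims: Sequence[PrescriptionClaim],
    index_date: dt.date,
    timepoint_days: int,
    table: DoseEquivalenceTable,
    config: StudyConfig,
) -> Optional[ExposureAssessment]:
    """Assessment for one patient-timepoint, or None when off therapy.

    Totals are computed twice, with eligibility re-derived under raw and
    cleaned fields separately; contributing claims and the route stratum come
    from the cleaned eligibility set.
    """
    elig_clean = eligible_claims(claims, index_date, timepoint_days, config, use_cleaned=True)
    if not elig_clean:
        return None
    elig_raw = eligible_claims(claims, index_date, timepoint_days, config, use_cleaned=False)
    seen = {c.claim_id: c for c in list(elig_clean) + list(elig_raw)}
    unmapped = [c.drug for c in seen.values() if (c.drug, c.formulation) not in table]
    if unmapped:
        raise UnmappedDrugError(unmapped)
    total_cleaned = sum(cpz_equivalent_mg(c, table, use_cleaned=True) for c in elig_clean)
    total_raw = sum(cpz_equivalent_mg(c, table, use_cleaned=False) for c in elig_raw)
    return ExposureAssessment(
        patient_id=patient_id,
        timepoint_days=timepoint_days,
        contributing_claim_ids=tuple(c.claim_id for c in elig_clean),
        route_class=classify_route(elig_clean),
        n_drugs=len({c.drug for c in elig_clean}),
        total_cpz_mg_raw=total_raw,
        total_cpz_mg_cleaned=total_cleaned,
        modified_by_cleaning=abs(total_cleaned - total_raw) > config.dose_change_tolerance_mg,
    )


def assess_cohort(
    members: Iterable[CohortMember],
    claims: Iterable[PrescriptionClaim],
    table: DoseEquivalenceTable,
    config: StudyConfig,
) -> list:
    """All assessments for every member at every reachable configured timepoint.

    A member is assessed at a timepoint only when follow-up (censored at
    death) reaches it; patients with no eligible claims at a timepoint emit
    no assessment there (off therapy).
    """
    by_patient: Dict[str, list] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    out = []
    for m in sorted(members, key=lambda m: m.patient_id):
        cl = sorted(by_patient.get(m.patient_id, []), key=lambda c: (c.dispense_date, c.claim_id))
        for t in config.timepoints_days:
            if m.followup_end < m.index_date + dt.timedelta(days=t):
                continue
            a = assess(m.patient_id, cl, m.index_date, t, table, config)
            if a is not None:
                out.append(a)
    return out
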