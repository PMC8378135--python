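"""Seeded synthetic claims generator with per-claim ground truth.

The generator emulates the *structure* of provincial dispensing-claims data
for antipsychotic initiators — patients, dispensing events with strength,
quantity, day's supply, dates and costs, plus the field-error modes the
cleaning rules are designed to repair — without attempting to reproduce any
real-population result. Patient-level defaults mirror the published study
conditions: route mix 97/2/1/0.5 (oral / regular injectable / multiple /
long-acting injectable; stored as published and normalised internally since
the rounded shares sum to 100.5%), 81% atypical initiation, 14% concurrent
prescriptions at initiation, and per-route day's-supply error shares of
3/16/36/42%.

Three error archetypes are injected, each recorded in the ground truth:

* ``ds_one_day_injection`` — a long-acting injection billed with day's
  supply 1 instead of its dosing interval (e.g. 1 vs 28 days);
* ``quantity_cost_mismatch`` — a short-acting injectable billed as
  "1 unit" while the costs reflect the true dispensed volume;
* ``ds_too_short`` — an oral day's supply far below the dispensed amount.

Truthful regimens are constructed to be fixed points of the cleaning rules
(quantity = 5 units per supply day for oral and short-acting claims; the
minimum dosing interval as the true long-acting day's supply, with injection
gaps at or above it), so that with error probabilities at zero the cleaner
reports no modifications and every injected error is attributable.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .model import (
    ConfigError,
    Formulation,
    Patient,
    PrescriptionClaim,
    Route,
    RouteClass,
    StudyConfig,
    sort_claims,
)

__all__ = [
    "GeneratorConfig",
    "CatalogDrug",
    "ClaimTruth",
    "PatientTruth",
    "SyntheticGroundTruth",
    "load_drug_catalog",
    "generate",
    "inject_errors",
    "truth_exposure",
]

ROUTE_CLASSES = (
    RouteClass.ORAL,
    RouteClass.REGULAR_INJECTABLE,
    RouteClass.LONG_ACTING_INJECTABLE,
    RouteClass.MULTIPLE,
)

DS_TOO_SHORT = "ds_too_short"
DS_ONE_DAY = "ds_one_day_injection"
QTY_COST_MISMATCH = "quantity_cost_mismatch"
NO_ERROR = "none"


@dataclass(frozen=True)
class CatalogDrug:
    drug: str
    route: Route
    formulation: Formulation
    strength_mg: float
    unit_cost: float
    atypical: bool
    min_interval_days: Optional[int] = None


def load_drug_catalog() -> list:
    """Bundled catalogue of ~12 antipsychotics spanning routes and formulations."""
    path = importlib.resources.files("apdose.data").joinpath("drug_catalog.csv")
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        mi = r.min_interval_days
        out.append(
            CatalogDrug(
                drug=r.drug,
                route=Route(r.route),
                formulation=Formulation(r.formulation),
                strength_mg=float(r.strength_mg),
                unit_cost=float(r.unit_cost),
                atypical=bool(r.atypical),
                min_interval_days=None if pd.isna(mi) else int(mi),
            )
        )
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort; defaults are the published shares."""

    n_patients: int = 1000
    accrual_start: dt.date = dt.date(2009, 1, 1)
    accrual_end: dt.date = dt.date(2012, 12, 31)
    route_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "oral": 0.97,
            "regular_injectable": 0.02,
            "multiple": 0.01,
            "long_acting_injectable": 0.005,
        }
    )
    atypical_share: float = 0.81
    concurrency_prob: float = 0.14
    error_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "oral": 0.03,
            "regular_injectable": 0.16,
            "long_acting_injectable": 0.36,
            "multiple": 0.42,
        }
    )
    rectal_share: float = 0.01  # of oral-class primary drugs
    long_gap_prob: float = 0.05  # oral refill gaps beyond the 100-day window
    discontinuation_prob: float = 0.06  # per refill
    one_year_mortality: float = 0.20
    under_age_prob: float = 0.05
    no_dementia_prob: float = 0.08
    prior_use_prob: float = 0.05
    single_fill_prob: float = 0.03
    followup_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.atypical_share, self.concurrency_prob, self.rectal_share,
            self.long_gap_prob, self.discontinuation_prob, self.one_year_mortality,
            self.under_age_prob, self.no_dementia_prob, self.prior_use_prob,
            self.single_fill_prob,
        ] + list(self.route_mix.values()) + list(self.error_probs.values())
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        missing = {rc.value for rc in ROUTE_CLASSES} - set(self.route_mix)
        if missing or sum(self.route_mix.values()) <= 0:
            raise ConfigError("route_mix must cover all four route classes with positive mass")
        if {rc.value for rc in ROUTE_CLASSES} - set(self.error_probs):
            raise ConfigError("error_probs must cover all four route classes")

    def normalized_route_mix(self) -> Dict[str, float]:
        s = sum(self.route_mix.values())
        return {k: v / s for k, v in self.route_mix.items()}


@dataclass
class ClaimTruth:
    claim_id: str
    patient_id: str
    true_quantity: float
    true_days_supply: int
    error: str = NO_ERROR


@dataclass
class PatientTruth:
    patient_id: str
    route_class: RouteClass
    concurrent: bool
    atypical: bool
    error: str = NO_ERROR
    under_age: bool = False
    no_dementia: bool = False
    prior_use: bool = False
    single_fill: bool = False


@dataclass
class SyntheticGroundTruth:
    claims: Dict[str, ClaimTruth]
    patients: Dict[str, PatientTruth]

    def claims_frame(self) -> pd.DataFrame:
        cols = ["claim_id", "patient_id", "true_quantity", "true_days_supply", "error"]
        return pd.DataFrame(
            [self.claims[k].__dict__ for k in sorted(self.claims)], columns=cols
        )

    def patients_frame(self) -> pd.DataFrame:
        cols = ["patient_id", "route_class", "concurrent", "atypical", "error",
                "under_age", "no_dementia", "prior_use", "single_fill"]
        rows = []
        for k in sorted(self.patients):
            d = dict(self.patients[k].__dict__)
            d["route_class"] = d["route_class"].value
            rows.append(d)
        return pd.DataFrame(rows, columns=cols)


def _catalog_groups(catalog: Sequence[CatalogDrug]):
    oral = [d for d in catalog if d.route is Route.ORAL]
    rectal = [d for d in catalog if d.route is Route.RECTAL]
    sa = [d for d in catalog if d.route is Route.INJECTABLE and d.formulation is Formulation.IMMEDIATE]
    lai = [d for d in catalog if d.formulation is Formulation.LONG_ACTING]
    return oral, rectal, sa, lai


def _pick(rng: np.random.Generator, drugs: Sequence[CatalogDrug]) -> CatalogDrug:
    return drugs[int(rng.integers(0, len(drugs)))]


def _pick_by_atypicality(rng, drugs, atypical: bool) -> CatalogDrug:
    sub = [d for d in drugs if d.atypical == atypical] or list(drugs)
    return _pick(rng, sub)


class _Regimen:
    """True dispensing parameters for one drug line."""

    def __init__(self, drug: CatalogDrug, rng: np.random.Generator, long_gap_prob: float):
        self.drug = drug
        self.long_gap_prob = long_gap_prob
        if drug.formulation is Formulation.LONG_ACTING:
            self.days_supply = int(drug.min_interval_days)
            self.quantity = 2.0 if drug.drug == "risperidone_la" else 1.0
        elif drug.route is Route.INJECTABLE:
            self.days_supply = 7
            self.quantity = 5.0 * self.days_supply
        else:
            self.days_supply = 30 if rng.random() < 0.75 else 90
            self.quantity = 5.0 * self.days_supply

    def gap(self, rng: np.random.Generator) -> int:
        d = self.drug
        if d.formulation is Formulation.LONG_ACTING:
            return self.days_supply + int(rng.integers(0, 8))
        if d.route is Route.INJECTABLE:
            return max(1, self.days_supply + int(rng.integers(-2, 6)))
        if rng.random() < self.long_gap_prob:
            return 101 + int(rng.integers(0, 50))
        return max(1, self.days_supply + int(rng.integers(-3, 11)))


def generate(config: GeneratorConfig):
    """Generate (patients, claims, ground truth), deterministically per seed."""
    rng = np.random.default_rng(config.seed)
    catalog = load_drug_catalog()
    oral_drugs, rectal_drugs, sa_drugs, lai_drugs = _catalog_groups(catalog)
    mix = config.normalized_route_mix()
    class_probs = np.array([mix[rc.value] for rc in ROUTE_CLASSES])
    p_mult = mix[RouteClass.MULTIPLE.value]
    conc_single = min(1.0, max(0.0, (config.concurrency_prob - p_mult) / (1.0 - p_mult)))
    window_days = (config.accrual_end - config.accrual_start).days
    mortality_scale = (
        None
        if config.one_year_mortality <= 0
        else config.followup_days / -math.log(1.0 - config.one_year_mortality)
    )

    patients: List[Patient] = []
    claims: List[PrescriptionClaim] = []
    plan: List[tuple] = []  # (claim_id, archetype, emitted_value)
    patient_truth: Dict[str, PatientTruth] = {}
    counter = 0

    def emit(pid: str, drug: CatalogDrug, date: dt.date, qty: float, ds: int) -> str:
        nonlocal counter
        cid = f"C{counter:07d}"
        counter += 1
        claims.append(
            PrescriptionClaim(
                claim_id=cid,
                patient_id=pid,
                drug=drug.drug,
                route=drug.route,
                formulation=drug.formulation,
                strength_mg=drug.strength_mg,
                quantity=qty,
                days_supply=ds,
                dispense_date=date,
                unit_cost=drug.unit_cost,
                total_cost=round(qty * drug.unit_cost, 2),
            )
        )
        return cid

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        route_class = ROUTE_CLASSES[int(rng.choice(len(ROUTE_CLASSES), p=class_probs))]
        under_age = rng.random() < config.under_age_prob
        no_dementia = rng.random() < config.no_dementia_prob
        prior_use = rng.random() < config.prior_use_prob
        single_fill = rng.random() < config.single_fill_prob
        concurrent = (
            True if route_class is RouteClass.MULTIPLE else rng.random() < conc_single
        )
        has_error = rng.random() < config.error_probs[route_class.value]

        index = config.accrual_start + dt.timedelta(days=int(rng.integers(0, window_days + 1)))
        age = 63 + int(rng.integers(0, 3)) if under_age else 66 + int(rng.integers(0, 30))
        birth = index - relativedelta(years=age) - dt.timedelta(days=int(rng.integers(0, 365)))
        death: Optional[dt.date] = None
        if mortality_scale is not None:
            d_days = int(math.ceil(rng.exponential(mortality_scale)))
            if d_days <= config.followup_days:
                death = index + dt.timedelta(days=d_days)

        atypical = rng.random() < config.atypical_share
        if route_class is RouteClass.ORAL:
            if rectal_drugs and rng.random() < config.rectal_share:
                primary = _pick(rng, rectal_drugs)
                atypical = primary.atypical
            else:
                primary = _pick_by_atypicality(rng, oral_drugs, atypical)
            secondary_pool = [d for d in oral_drugs if d.drug != primary.drug]
        elif route_class is RouteClass.REGULAR_INJECTABLE:
            primary = _pick_by_atypicality(rng, sa_drugs, atypical)
            secondary_pool = [d for d in sa_drugs if d.drug != primary.drug] or [
                d for d in oral_drugs if d.drug != primary.drug
            ]
        elif route_class is RouteClass.LONG_ACTING_INJECTABLE:
            primary = _pick_by_atypicality(rng, lai_drugs, atypical)
            # a concurrent depot must not have a longer minimum interval than the
            # primary's injection cycle, or its supply would truly be cut short
            secondary_pool = [
                d for d in lai_drugs
                if d.drug != primary.drug and d.min_interval_days <= primary.min_interval_days
            ]
        else:  # multiple routes: oral primary + injectable secondary at index
            primary = _pick_by_atypicality(rng, oral_drugs, atypical)
            pool = sa_drugs if rng.random() < 0.5 else lai_drugs
            secondary_pool = [d for d in pool if d.drug != primary.drug] or list(pool)

        regimen = _Regimen(primary, rng, config.long_gap_prob)
        oral_error_gap = (
            101 + int(rng.integers(0, 30))
            if has_error
            and route_class is RouteClass.ORAL
            else None
        )

        # primary line
        t = index
        first = True
        first_claim_id = None
        while True:
            cid = emit(pid, primary, t, regimen.quantity, regimen.days_supply)
            if first:
                first_claim_id = cid
                first = False
            if single_fill:
                break
            if rng.random() < config.discontinuation_prob:
                break
            gap = oral_error_gap if (oral_error_gap is not None and t == index) else regimen.gap(rng)
            t = t + dt.timedelta(days=gap)
            if (t - index).days > config.followup_days:
                break
            if death is not None and t >= death:
                break

        # concurrent second drug, dispensed once on the index date
        secondary_claim_id = None
        secondary = None
        if concurrent and secondary_pool:
            secondary = _pick(rng, secondary_pool)
            sec_reg = _Regimen(secondary, rng, config.long_gap_prob)
            secondary_claim_id = emit(pid, secondary, index, sec_reg.quantity, sec_reg.days_supply)

        # prior dispensing before the accrual window (washout violator)
        if prior_use:
            prior_date = config.accrual_start - dt.timedelta(days=10 + int(rng.integers(0, 290)))
            emit(pid, primary, prior_date, regimen.quantity, regimen.days_supply)

        # plan the injected error
        archetype = NO_ERROR
        if has_error:
            if route_class is RouteClass.MULTIPLE and secondary_claim_id is not None:
                target, target_drug = secondary_claim_id, secondary
            else:
                target, target_drug = first_claim_id, primary
            if target_drug.formulation is Formulation.LONG_ACTING:
                archetype = DS_ONE_DAY
                plan.append((target, archetype, 1))
            elif target_drug.route is Route.INJECTABLE:
                archetype = QTY_COST_MISMATCH
                plan.append((target, archetype, 1.0))
            else:
                archetype = DS_TOO_SHORT
                plan.append((target, archetype, 1 + int(rng.integers(0, 7))))

        patients.append(Patient(pid, birth, death, dementia=not no_dementia))
        patient_truth[pid] = PatientTruth(
            patient_id=pid,
            route_class=route_class,
            concurrent=concurrent,
            atypical=atypical,
            error=archetype,
            under_age=under_age,
            no_dementia=no_dementia,
            prior_use=prior_use,
            single_fill=single_fill,
        )

    claims, claim_truth = inject_errors(claims, config, rng=None, plan=plan)
    return patients, sort_claims(claims), SyntheticGroundTruth(claim_truth, patient_truth)


def inject_errors(
    claims: Sequence[PrescriptionClaim],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    plan: Optional[Sequence[tuple]] = None,
):
    """Flip claim fields per archetype; returns (claims, claim-level ground truth).

    With an explicit ``plan`` (as produced by :func:`generate`) the listed
    (claim_id, archetype, emitted_value) flips are applied. Without one, the
    patient route classes are derived from the index-day claims, error
    patients are sampled with the configured per-route probabilities using
    ``rng``, and the archetype-appropriate index-day claim is flipped.
    """
    claims = list(claims)
    by_id = {c.claim_id: c for c in claims}
    truth = {
        c.claim_id: ClaimTruth(c.claim_id, c.patient_id, c.quantity, c.days_supply)
        for c in claims
    }
    if plan is None:
        if rng is None:
            raise ConfigError("inject_errors without a plan requires an rng")
        plan = _derive_plan(claims, config, rng)
    for claim_id, archetype, value in plan:
        c = by_id[claim_id]
        t = truth[claim_id]
        t.error = archetype
        if archetype in (DS_TOO_SHORT, DS_ONE_DAY):
            c.days_supply = int(value)
            c.cleaned_days_supply = int(value)
        elif archetype == QTY_COST_MISMATCH:
            c.quantity = float(value)
            c.cleaned_quantity = float(value)
        else:
            raise ConfigError(f"unknown error archetype '{archetype}'")
    return claims, truth


def _derive_plan(claims, config, rng):
    from .exposure import _category  # claim -> route category

    by_patient: Dict[str, list] = {}
    for c in claims:
        by_patient.setdefault(c.patient_id, []).append(c)
    plan = []
    for pid in sorted(by_patient):
        group = sorted(by_patient[pid], key=lambda c: (c.dispense_date, c.claim_id))
        first_day = group[0].dispense_date
        index_claims = [c for c in group if c.dispense_date == first_day]
        cats = {_category(c) for c in index_claims}
        rc = cats.pop() if len(cats) == 1 else RouteClass.MULTIPLE
        if rng.random() >= config.error_probs[rc.value]:
            continue
        target = next(
            (c for c in index_claims if c.route is Route.INJECTABLE), index_claims[0]
        )
        if target.formulation is Formulation.LONG_ACTING:
            plan.append((target.claim_id, DS_ONE_DAY, 1))
        elif target.route is Route.INJECTABLE:
            plan.append((target.claim_id, QTY_COST_MISMATCH, 1.0))
        else:
            plan.append((target.claim_id, DS_TOO_SHORT, 1 + int(rng.integers(0, 7))))
    return plan


def truth_claims(
    claims: Sequence[PrescriptionClaim], ground_truth: SyntheticGroundTruth
) -> list:
    """Copies of the claims with quantity/day's supply restored to their true values."""
    out = []
    for c in claims:
        t = ground_truth.claims[c.claim_id]
        c2 = c.copy()
        c2.quantity = t.true_quantity
        c2.days_supply = t.true_days_supply
        c2.cleaned_quantity = t.true_quantity
        c2.cleaned_days_supply = t.true_days_supply
        c2.quantity_modified = False
        c2.days_supply_modified = False
        out.append(c2)
    return out


def truth_exposure(patients, claims, ground_truth, table, config: StudyConfig):
    """Reference assessments computed from the true fields (no cleaning needed).

    The recovery target for the cleaning rules: cohort logic uses dates only,
    so membership is identical to the emitted data, and totals are computed by
    the same exposure operations on the true quantity/day's-supply values.
    """
    from .cohort import build_cohort
    from .exposure import assess_cohort

    true_cl = truth_claims(claims, ground_truth)
    members, _ = build_cohort(patients, true_cl, config)
    return assess_cohort(members, true_cl, table, config)
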