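"""Domain types for antipsychotic dispensing claims and study configuration.

The central objects are :class:`PrescriptionClaim` (one dispensing event,
carrying both the raw fields as billed and the cleaned fields produced by the
data-cleaning rules), :class:`Patient`, the two configuration tables
(:class:`DoseEquivalenceTable`, :class:`DosingIntervalTable`) and
:class:`StudyConfig`, which holds every constant of the study design: the
accrual window, the one-year washout, the 100-day refill and lookback windows,
the divide-by-5 day's-supply fallback, and the assessment timepoints.

All durations are exact day differences on calendar dates; drug names are
canonicalised (trimmed, lower-cased, whitespace collapsed to underscores)
before any matching.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
import re
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Route",
    "Formulation",
    "RouteClass",
    "PrescriptionClaim",
    "Patient",
    "DoseEquivalenceTable",
    "DosingIntervalTable",
    "StudyConfig",
    "ApdoseError",
    "SchemaError",
    "ClaimValidationError",
    "ConfigError",
    "ContractError",
    "DataIntegrityError",
    "canonical_drug",
    "completed_years",
    "round_half_up",
]


class ApdoseError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(ApdoseError):
    """An input file is missing a required column."""


class ClaimValidationError(ApdoseError):
    """One or more rows violate a type invariant.

    ``errors`` is a list of ``(row_label, field, message)`` tuples; row_label
    is the claim_id when available, otherwise the 0-based row number.
    """

    def __init__(self, errors: Sequence[tuple]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}, field {f}: {m}" for r, f, m in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


class ConfigError(ApdoseError):
    """A configuration table or parameter is invalid."""


class ContractError(ApdoseError):
    """An operation was called outside its stated precondition."""


class DataIntegrityError(ApdoseError):
    """Cross-table referential integrity violated (e.g. orphan claims)."""


class Route(str, enum.Enum):
    ORAL = "oral"
    RECTAL = "rectal"
    INJECTABLE = "injectable"


class Formulation(str, enum.Enum):
    IMMEDIATE = "immediate"
    LONG_ACTING = "long_acting"


class RouteClass(str, enum.Enum):
    """Administration-route stratum used for reporting."""

    ORAL = "oral"
    REGULAR_INJECTABLE = "regular_injectable"
    LONG_ACTING_INJECTABLE = "long_acting_injectable"
    MULTIPLE = "multiple"


_WS = re.compile(r"\s+")


def canonical_drug(name: str) -> str:
    """Canonical ingredient token: trimmed, lower-cased, spaces -> underscores."""
    return _WS.sub("_", str(name).strip().lower())


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (day's-supply rounding)."""
    return int(math.floor(x + 0.5))


def completed_years(birth: dt.date, on: dt.date) -> int:
    """Age in completed years on a given date."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


@dataclass
class PrescriptionClaim:
    """One dispensing event with raw (as-billed) and cleaned fields.

    ``strength_mg`` is milligrams of ingredient per dispensed unit (per tablet,
    or per mL for injectables); ``quantity`` is the number of dispensed units;
    ``unit_cost`` is the billable cost per unit and ``total_cost`` the total
    billed amount (either may be missing). Cleaned fields start equal to the
    raw fields with both modified flags false; only the cleaning rules touch
    them.
    """

    claim_id: str
    patient_id: str
    drug: str
    route: Route
    formulation: Formulation
    strength_mg: float
    quantity: float
    days_supply: int
    dispense_date: dt.date
    unit_cost: Optional[float] = None
    total_cost: Optional[float] = None
    cleaned_quantity: float = None  # type: ignore[assignment]
    cleaned_days_supply: int = None  # type: ignore[assignment]
    quantity_modified: bool = False
    days_supply_modified: bool = False

    def __post_init__(self) -> None:
        self.drug = canonical_drug(self.drug)
        self.route = Route(self.route)
        self.formulation = Formulation(self.formulation)
        if self.cleaned_quantity is None:
            self.cleaned_quantity = self.quantity
        if self.cleaned_days_supply is None:
            self.cleaned_days_supply = self.days_supply
        errors = self.invariant_errors()
        if errors:
            raise ClaimValidationError([(self.claim_id, f, m) for f, m in errors])

    def invariant_errors(self) -> list:
        """Return ``(field, message)`` for every violated invariant (no raise)."""
        errs = []
        if self.formulation is Formulation.LONG_ACTING and self.route is not Route.INJECTABLE:
            errs.append(("formulation", "long_acting is valid only with route=injectable"))
        if not self.strength_mg > 0:
            errs.append(("strength_mg", "must be > 0"))
        if not self.quantity > 0:
            errs.append(("quantity", "must be > 0"))
        if int(self.days_supply) != self.days_supply or self.days_supply < 1:
            errs.append(("days_supply", "must be an integer >= 1"))
        if self.unit_cost is not None and self.unit_cost < 0:
            errs.append(("unit_cost", "must be >= 0 or missing"))
        if self.total_cost is not None and self.total_cost < 0:
            errs.append(("total_cost", "must be >= 0 or missing"))
        if not self.cleaned_quantity > 0:
            errs.append(("cleaned_quantity", "must be > 0"))
        if int(self.cleaned_days_supply) != self.cleaned_days_supply or self.cleaned_days_supply < 1:
            errs.append(("cleaned_days_supply", "must be an integer >= 1"))
        if not self.quantity_modified and self.cleaned_quantity != self.quantity:
            errs.append(("cleaned_quantity", "differs from quantity but quantity_modified is false"))
        if not self.days_supply_modified and self.cleaned_days_supply != self.days_supply:
            errs.append(
                ("cleaned_days_supply", "differs from days_supply but days_supply_modified is false")
            )
        return errs

    def copy(self) -> "PrescriptionClaim":
        return replace(self)


@dataclass
class Patient:
    patient_id: str
    birth_date: dt.date
    death_date: Optional[dt.date] = None
    dementia: bool = False

    def __post_init__(self) -> None:
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ClaimValidationError(
                [(self.patient_id, "death_date", "death_date precedes birth_date")]
            )


class DoseEquivalenceTable:
    """Per (drug, formulation) conversion factor to chlorpromazine equivalents.

    ``cpz_factor`` is mg of chlorpromazine pharmacologically comparable to
    1 mg of the drug per day; the table must contain the identity entry
    (chlorpromazine, immediate) = 1.0.
    """

    def __init__(self, entries: Mapping[tuple, float]):
        self._entries = {}
        for (drug, form), f in entries.items():
            key = (canonical_drug(drug), Formulation(form))
            if not f > 0:
                raise ConfigError(f"cpz_factor for {key[0]}/{key[1].value} must be > 0, got {f}")
            self._entries[key] = float(f)
        ident = self._entries.get(("chlorpromazine", Formulation.IMMEDIATE))
        if ident != 1.0:
            raise ConfigError(
                "equivalence table must contain (chlorpromazine, immediate) with cpz_factor = 1.0"
            )

    def factor(self, drug: str, formulation: Formulation) -> float:
        key = (canonical_drug(drug), Formulation(formulation))
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(f"{key[0]}/{key[1].value}") from None

    def __contains__(self, key: tuple) -> bool:
        drug, form = key
        return (canonical_drug(drug), Formulation(form)) in self._entries

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)


class DosingIntervalTable:
    """Minimum dosing interval in days per long-acting injectable drug."""

    def __init__(self, entries: Mapping[str, int]):
        self._entries = {}
        for drug, days in entries.items():
            d = canonical_drug(drug)
            if int(days) != days or days < 1:
                raise ConfigError(f"min_interval_days for {d} must be an integer >= 1, got {days}")
            self._entries[d] = int(days)

    def interval(self, drug: str) -> int:
        try:
            return self._entries[canonical_drug(drug)]
        except KeyError:
            raise ConfigError(
                f"no minimum dosing interval configured for long-acting drug '{canonical_drug(drug)}'"
            ) from None

    def __contains__(self, drug: str) -> bool:
        return canonical_drug(drug) in self._entries

    def items(self):
        return self._entries.items()


@dataclass
class StudyConfig:
    """All constants of the study design.

    Defaults follow the published design: accrual 2009-2012, one-year washout,
    age >= 66 at entry, 12 months of follow-up assessed at initiation (day 0),
    month 6 (day 182) and month 12 (day 365), a 100-day refill window for the
    oral day's-supply rule, a 100-day lookback for exposure eligibility, and a
    divide-by-5 quantity fallback (5 units/day is the maximum dosing rate
    assumed for any antipsychotic regimen).
    """

    accrual_start: dt.date = dt.date(2009, 1, 1)
    accrual_end: dt.date = dt.date(2012, 12, 31)
    washout_days: int = 365
    min_age_years: int = 66
    followup_days: int = 365
    timepoints_days: tuple = (0, 182, 365)
    lookback_days: int = 100
    next_fill_window_days: int = 100
    oral_fallback_divisor: float = 5.0
    cost_mismatch_tolerance: float = 0.05
    dose_change_tolerance_mg: float = 1e-9

    def __post_init__(self) -> None:
        self.timepoints_days = tuple(int(t) for t in self.timepoints_days)
        if self.accrual_end < self.accrual_start:
            raise ConfigError("accrual_end precedes accrual_start")
        for name in ("washout_days", "followup_days", "lookback_days",
                     "next_fill_window_days", "oral_fallback_divisor"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.cost_mismatch_tolerance < 0 or self.dose_change_tolerance_mg < 0:
            raise ConfigError("tolerances must be >= 0")
        for t in self.timepoints_days:
            if not 0 <= t <= self.followup_days:
                raise ConfigError(f"timepoint {t} outside [0, followup_days]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        for k, v in d.items():
            if k not in valid:
                raise ConfigError(f"unknown study-config key '{k}'")
            if k in ("accrual_start", "accrual_end") and isinstance(v, str):
                v = dt.date.fromisoformat(v)
            kwargs[k] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dt.date):
                v = v.isoformat()
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d


def sort_claims(claims: Iterable[PrescriptionClaim]) -> list:
    """Canonical claim order: (patient_id, dispense_date, claim_id)."""
    return sorted(claims, key=lambda c: (c.patient_id, c.dispense_date, c.claim_id))
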