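"""CSV/YAML readers and writers for claims, patients, config tables and outputs.

All tabular I/O is comma-separated UTF-8 with a header row and ISO-8601 dates.
``read_claims`` validates every row against the claim invariants and reports
*all* offending rows (1-based data-row numbers) rather than stopping at the
first. Bundled default equivalence and dosing-interval tables are
reconstructions from the potency-equivalence literature and are fully
user-replaceable.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
import math
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .model import (
    ClaimValidationError,
    ConfigError,
    DoseEquivalenceTable,
    DosingIntervalTable,
    Formulation,
    Patient,
    PrescriptionClaim,
    Route,
    SchemaError,
    sort_claims,
)

CLAIM_COLUMNS = (
    "claim_id",
    "patient_id",
    "drug",
    "route",
    "formulation",
    "strength_mg",
    "quantity",
    "days_supply",
    "dispense_date",
    "unit_cost",
    "total_cost",
)
CLEANED_COLUMNS = (
    "cleaned_quantity",
    "cleaned_days_supply",
    "quantity_modified",
    "days_supply_modified",
)
PATIENT_COLUMNS = ("patient_id", "birth_date", "death_date", "dementia")


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _date(v) -> dt.date:
    if isinstance(v, dt.date) and not isinstance(v, dt.datetime):
        return v
    if isinstance(v, dt.datetime):
        return v.date()
    return dt.date.fromisoformat(str(v))


def _bool(v) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "t", "yes")


def read_claims(path, schema: Optional[Mapping[str, str]] = None) -> list:
    """Read a dispensing-claims CSV into validated :class:`PrescriptionClaim` objects.

    ``schema`` optionally maps canonical column names to the file's column
    names. Cleaned-field columns are honoured when present (round-tripping a
    cleaned file); otherwise cleaned fields start equal to raw fields. Output
    is sorted by (patient_id, dispense_date, claim_id).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in CLAIM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_cleaned = all(c in df.columns for c in CLEANED_COLUMNS)

    claims, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict()
        label = r.get("claim_id") or str(i)
        try:
            kwargs = dict(
                claim_id=str(r["claim_id"]),
                patient_id=str(r["patient_id"]),
                drug=r["drug"],
                route=Route(str(r["route"]).strip().lower()),
                formulation=Formulation(str(r["formulation"]).strip().lower()),
                strength_mg=float(r["strength_mg"]),
                quantity=float(r["quantity"]),
                days_supply=int(float(r["days_supply"])),
                dispense_date=_date(r["dispense_date"]),
                unit_cost=_opt_float(r["unit_cost"]),
                total_cost=_opt_float(r["total_cost"]),
            )
            if has_cleaned:
                kwargs.update(
                    cleaned_quantity=float(r["cleaned_quantity"]),
                    cleaned_days_supply=int(float(r["cleaned_days_supply"])),
                    quantity_modified=_bool(r["quantity_modified"]),
                    days_supply_modified=_bool(r["days_supply_modified"]),
                )
            claims.append(PrescriptionClaim(**kwargs))
        except ClaimValidationError as e:
            errors.extend((f"{i} (claim {label})", f, m) for _, f, m in e.errors)
        except (ValueError, KeyError) as e:
            errors.append((f"{i} (claim {label})", "-", str(e)))
    if errors:
        raise ClaimValidationError(errors)
    return sort_claims(claims)


def write_claims(claims: Iterable[PrescriptionClaim], path) -> None:
    rows = []
    for c in sort_claims(claims):
        rows.append(
            dict(
                claim_id=c.claim_id,
                patient_id=c.patient_id,
                drug=c.drug,
                route=c.route.value,
                formulation=c.formulation.value,
                strength_mg=c.strength_mg,
                quantity=c.quantity,
                days_supply=c.days_supply,
                dispense_date=c.dispense_date.isoformat(),
                unit_cost="" if c.unit_cost is None else c.unit_cost,
                total_cost="" if c.total_cost is None else c.total_cost,
                cleaned_quantity=c.cleaned_quantity,
                cleaned_days_supply=c.cleaned_days_supply,
                quantity_modified=c.quantity_modified,
                days_supply_modified=c.days_supply_modified,
            )
        )
    cols = list(CLAIM_COLUMNS) + list(CLEANED_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_patients(path) -> list:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        out.append(
            Patient(
                patient_id=str(d["patient_id"]),
                birth_date=_date(d["birth_date"]),
                death_date=None if d["death_date"] == "" else _date(d["death_date"]),
                dementia=_bool(d["dementia"]),
            )
        )
    return sorted(out, key=lambda p: p.patient_id)


def write_patients(patients: Iterable[Patient], path) -> None:
    rows = [
        dict(
            patient_id=p.patient_id,
            birth_date=p.birth_date.isoformat(),
            death_date="" if p.death_date is None else p.death_date.isoformat(),
            dementia=p.dementia,
        )
        for p in sorted(patients, key=lambda p: p.patient_id)
    ]
    pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(path, index=False)


def read_equivalence_table(path) -> DoseEquivalenceTable:
    """Load a dose-equivalence table from CSV (drug,formulation,cpz_factor) or YAML."""
    p = str(path)
    if p.endswith((".yaml", ".yml")):
        with open(p, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = {(e["drug"], e["formulation"]): float(e["cpz_factor"]) for e in raw}
    else:
        df = pd.read_csv(p)
        for col in ("drug", "formulation", "cpz_factor"):
            if col not in df.columns:
                raise SchemaError(f"missing required column(s): {col}")
        entries = {
            (r.drug, r.formulation): float(r.cpz_factor) for r in df.itertuples(index=False)
        }
    try:
        return DoseEquivalenceTable(entries)
    except ValueError as e:  # bad formulation token
        raise ConfigError(str(e)) from None


def read_intervals_table(path) -> DosingIntervalTable:
    """Load a minimum-dosing-interval table from CSV (drug,min_interval_days) or YAML."""
    p = str(path)
    if p.endswith((".yaml", ".yml")):
        with open(p, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = dict(raw)
    else:
        df = pd.read_csv(p)
        for col in ("drug", "min_interval_days"):
            if col not in df.columns:
                raise SchemaError(f"missing required column(s): {col}")
        entries = {r.drug: int(r.min_interval_days) for r in df.itertuples(index=False)}
    return DosingIntervalTable(entries)


def _data_path(name: str):
    return importlib.resources.files("apdose.data").joinpath(name)


def default_equivalence_table() -> DoseEquivalenceTable:
    """Bundled chlorpromazine-equivalence defaults (reconstructed, replaceable)."""
    return read_equivalence_table(_data_path("equivalence.csv"))


def default_intervals_table() -> DosingIntervalTable:
    """Bundled minimum dosing intervals for long-acting injectables."""
    return read_intervals_table(_data_path("dosing_intervals.csv"))


EXPOSURE_COLUMNS = (
    "patient_id",
    "timepoint_days",
    "route_class",
    "n_claims",
    "n_drugs",
    "total_cpz_mg_raw",
    "total_cpz_mg_cleaned",
    "modified_by_cleaning",
    "contributing_claim_ids",
)


def write_exposure_table(assessments, path) -> None:
    """One row per (patient, timepoint); round-trips losslessly via read_exposure_table."""
    rows = []
    for a in sorted(assessments, key=lambda a: (a.patient_id, a.timepoint_days)):
        rows.append(
            dict(
                patient_id=a.patient_id,
                timepoint_days=a.timepoint_days,
                route_class=a.route_class.value,
                n_claims=len(a.contributing_claim_ids),
                n_drugs=a.n_drugs,
                total_cpz_mg_raw=repr(a.total_cpz_mg_raw),
                total_cpz_mg_cleaned=repr(a.total_cpz_mg_cleaned),
                modified_by_cleaning=a.modified_by_cleaning,
                contributing_claim_ids=";".join(a.contributing_claim_ids),
            )
        )
    pd.DataFrame(rows, columns=list(EXPOSURE_COLUMNS)).to_csv(path, index=False)


def read_exposure_table(path) -> list:
    from .exposure import ExposureAssessment  # deferred: exposure imports model only

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        ids = tuple(d["contributing_claim_ids"].split(";")) if d["contributing_claim_ids"] else ()
        from .model import RouteClass

        out.append(
            ExposureAssessment(
                patient_id=str(d["patient_id"]),
                timepoint_days=int(d["timepoint_days"]),
                contributing_claim_ids=ids,
                route_class=RouteClass(d["route_class"]),
                n_drugs=int(d["n_drugs"]),
                total_cpz_mg_raw=float(d["total_cpz_mg_raw"]),
                total_cpz_mg_cleaned=float(d["total_cpz_mg_cleaned"]),
                modified_by_cleaning=_bool(d["modified_by_cleaning"]),
            )
        )
    return out
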