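import datetime as dt

import pytest

from apdose import (
    DoseEquivalenceTable,
    DosingIntervalTable,
    Formulation,
    Patient,
    PrescriptionClaim,
    Route,
    StudyConfig,
    default_equivalence_table,
    default_intervals_table,
)

D0 = dt.date(2010, 6, 1)


def mk_claim(
    claim_id="C1",
    patient_id="P1",
    drug="risperidone",
    route=Route.ORAL,
    formulation=Formulation.IMMEDIATE,
    strength_mg=0.25,
    quantity=150.0,
    days_supply=30,
    dispense_date=D0,
    unit_cost=None,
    total_cost=None,
    **kw,
):
    return PrescriptionClaim(
        claim_id=claim_id,
        patient_id=patient_id,
        drug=drug,
        route=route,
        formulation=formulation,
        strength_mg=strength_mg,
        quantity=quantity,
        days_supply=days_supply,
        dispense_date=dispense_date,
        unit_cost=unit_cost,
        total_cost=total_cost,
        **kw,
    )


def mk_patient(patient_id="P1", age_at=80, on=D0, death_date=None, dementia=True):
    birth = dt.date(on.year - age_at, on.month, on.day)
    return Patient(patient_id, birth, death_date, dementia)


@pytest.fixture(scope="session")
def config():
    return StudyConfig()

@pytest.fixture(scope="session")
def equivalence():
    return default_equivalence_table()


@pytest.fixture(scope="session")
def intervals():
    return default_intervals_table()
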