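from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pharmaproc import (
    Category,
    DosageForm,
    MedicineSpec,
    PriceIndexSeries,
    ProcurementType,
    PurchaseRecord,
    Status,
    parse_month,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # module fixtures passed to @given tests are read-only
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def master() -> list[MedicineSpec]:
    return [
        MedicineSpec("A10", "Alphatax", 10.0, (DosageForm.TABLET,)),
        MedicineSpec("B25", "Betazol", 25.0, (DosageForm.AMPOULE,)),
        MedicineSpec("C440", "Gammamab", 440.0, (DosageForm.AMPOULE, DosageForm.CAPSULE)),
    ]


@pytest.fixture
def flat_index() -> PriceIndexSeries:
    months = pd.period_range("2013-01", "2019-12", freq="M")
    return PriceIndexSeries({m: 100.0 for m in months})


def make_record(
    code: str = "A10",
    month: str = "2015-06",
    category: Category = Category.HEALTH,
    quantity: int = 10,
    price: float = 2.0,
    procurement: ProcurementType = ProcurementType.COMPETITIVE,
    status: Status = Status.ACTIVE,
    entity: str = "E1",
) -> PurchaseRecord:
    return PurchaseRecord(
        medicine_code=code,
        purchase_date=parse_month(month),
        category=category,
        entity_id=entity,
        quantity_units=quantity,
        unit_price=price,
        procurement_type=procurement,
        status=status,
    )
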