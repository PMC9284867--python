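"""Core domain types for procurement ledgers.

A ledger is a list of :class:`PurchaseRecord`, one per procurement event
registered by a public buyer. Dates are handled at calendar-month
resolution throughout: inflation adjustment and annual aggregation never
need the day of month.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "Category",
    "DosageForm",
    "ProcurementType",
    "Status",
    "CATEGORY_ORDER",
    "MedicineSpec",
    "PurchaseRecord",
    "StudyConfig",
    "Month",
    "parse_month",
    "month_offset",
    "round_half_away",
]

Month = pd.Period  # monthly-frequency period, e.g. Period('2019-07', 'M')


class Category(str, enum.Enum):
    """Purchaser category of a federal procurement record."""

    EDUCATION = "ME"   # Ministry of Education (university hospitals)
    HEALTH = "MH"      # Ministry of Health
    DEFENSE = "MD"     # Ministry of Defense medical services
    OTHER = "OI"       # other institutions (mainly state/municipal health)

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Fixed deterministic order, also the benchmark tie-break order.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.EDUCATION, Category.HEALTH, Category.DEFENSE, Category.OTHER,
)


class DosageForm(str, enum.Enum):
    TABLET = "tablet"
    CAPSULE = "capsule"
    AMPOULE = "ampoule"

    def __str__(self) -> str:
        return self.value


class ProcurementType(str, enum.Enum):
    COMPETITIVE = "competitive"
    WAIVER = "waiver"
    NOT_REQUIRED = "not_required"

    def __str__(self) -> str:
        return self.value


class Status(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"

    def __str__(self) -> str:
        return self.value


def parse_month(text: str | Month) -> Month:
    """Parse an ISO ``YYYY-MM`` month string into a monthly Period."""
    if isinstance(text, pd.Period):
        if text.freqstr not in ("M", "ME"):
            raise ValueError(f"expected monthly period, got freq {text.freqstr!r}")
        return text
    text = str(text).strip()
    try:
        year, month = text.split("-")
        period = pd.Period(year=int(year), month=int(month), freq="M")
    except Exception as exc:  # noqa: BLE001 - uniform diagnostic
        raise ValueError(f"invalid month {text!r}, expected 'YYYY-MM'") from exc
    return period


def month_offset(later: Month, earlier: Month) -> int:
    """Number of months from ``earlier`` to ``later`` (signed)."""
    return (later - earlier).n


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used for all printed values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class MedicineSpec:
    """One medicine presentation: active ingredient at a fixed strength.

    ``dosage_forms`` may contain more than one form (e.g. a drug marketed
    both as ampoule and capsule at the same strength); analyses pool all
    forms of equal strength.
    """

    code: str
    name: str
    strength_mg: float
    dosage_forms: tuple[DosageForm, ...]

    def __post_init__(self) -> None:
        if self.strength_mg <= 0:
            raise ValueError(f"{self.code}: strength_mg must be > 0")
        if not self.dosage_forms:
            raise ValueError(f"{self.code}: at least one dosage form required")


@dataclass(frozen=True, slots=True)
class PurchaseRecord:
    """One procurement event: a buyer purchased ``quantity_units`` dispensing
    units of a medicine at a nominal ``unit_price`` (currency per unit)."""

    medicine_code: str
    purchase_date: Month
    category: Category
    entity_id: str
    quantity_units: int
    unit_price: float
    procurement_type: ProcurementType
    status: Status

    def __post_init__(self) -> None:
        if self.quantity_units < 1:
            raise ValueError("quantity_units must be >= 1")
        if self.unit_price <= 0:
            raise ValueError("unit_price must be > 0")

    @property
    def year(self) -> int:
        return self.purchase_date.year

    def with_price(self, price: float) -> "PurchaseRecord":
        return replace(self, unit_price=price)


class StudyConfig(BaseModel):
    """Study window and analysis rules.

    ``min_years_purchased`` is the inclusion rule: a medicine enters the
    analysis only if the ``inclusion_category`` bought it in at least that
    many distinct calendar years of the window.
    """

    window_start: str = "2013-01"
    window_end: str = "2019-12"
    min_years_purchased: int = 5
    inclusion_category: Category = Category.HEALTH
    reference_month: str = "2019-07"
    pattern_market_threshold: float = -0.5
    pattern_inelastic_threshold: float = 0.3
    pattern_min_years: int = 4

    @field_validator("window_start", "window_end", "reference_month")
    @classmethod
    def _valid_month(cls, v: str) -> str:
        parse_month(v)
        return v

    @model_validator(mode="after")
    def _valid_window(self) -> "StudyConfig":
        if not self.start <= self.end:
            raise ValueError("window_start must not be after window_end")
        n_years = self.end.year - self.start.year + 1
        if not 1 <= self.min_years_purchased <= n_years:
            raise ValueError(
                f"min_years_purchased must be in [1, {n_years}] for this window"
            )
        return self

    @property
    def start(self) -> Month:
        return parse_month(self.window_start)

    @property
    def end(self) -> Month:
        return parse_month(self.window_end)

    @property
    def reference(self) -> Month:
        return parse_month(self.reference_month)

    @property
    def years(self) -> range:
        return range(self.start.year, self.end.year + 1)


def master_by_code(master: Iterable[MedicineSpec]) -> Mapping[str, MedicineSpec]:
    """Index a master list by code, enforcing uniqueness."""
    out: dict[str, MedicineSpec] = {}
    for med in master:
        if med.code in out:
            raise ValueError(f"duplicate medicine code {med.code!r} in master list")
        out[med.code] = med
    return out
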