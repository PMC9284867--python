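"""Reading, validating and filtering purchase ledgers.

CSV schemas (exact headers):

* purchases: ``medicine_code,purchase_date,category,entity_id,quantity_units,unit_price,procurement_type,status``
  with ISO ``YYYY-MM`` dates, category tokens ``ME``/``MH``/``MD``/``OI``,
  decimal points and no thousands separators;
* medicine master: ``medicine_code,name,strength_mg,dosage_form`` where
  ``dosage_form`` may list several forms separated by ``/``.

Only *active* purchases made through *competitive* bidding enter the
analysis, and a medicine is analysed only if the inclusion category
bought it in enough distinct calendar years of the study window.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    Category,
    DosageForm,
    MedicineSpec,
    ProcurementType,
    PurchaseRecord,
    Status,
    StudyConfig,
    master_by_code,
    parse_month,
)

__all__ = [
    "LedgerValidationError",
    "RowIssue",
    "LedgerReadResult",
    "read_master",
    "read_purchases",
    "write_purchases",
    "filter_eligible",
    "select_medicines",
]

log = logging.getLogger(__name__)

PURCHASES_HEADER = [
    "medicine_code", "purchase_date", "category", "entity_id",
    "quantity_units", "unit_price", "procurement_type", "status",
]
MASTER_HEADER = ["medicine_code", "name", "strength_mg", "dosage_form"]


@dataclass(frozen=True)
class RowIssue:
    """A row-level validation failure (1-based data row number)."""

    row: int
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.message}"


class LedgerValidationError(ValueError):
    """Raised when a ledger file contains invalid rows (strict mode)."""

    def __init__(self, issues: Sequence[RowIssue], path: str | Path):
        self.issues = list(issues)
        preview = "; ".join(str(i) for i in self.issues[:5])
        more = "" if len(self.issues) <= 5 else f" (+{len(self.issues) - 5} more)"
        super().__init__(f"{path}: {len(self.issues)} invalid row(s): {preview}{more}")


@dataclass
class LedgerReadResult:
    """Validated records plus any rejected rows (skip mode only)."""

    records: list[PurchaseRecord]
    rejections: list[RowIssue] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _check_header(path: Path, actual: list[str], expected: list[str]) -> None:
    if list(actual) != expected:
        raise ValueError(
            f"{path}: malformed header {actual!r}, expected {expected!r}"
        )


def read_master(path: str | Path) -> list[MedicineSpec]:
    """Read a medicine master list CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _check_header(path, list(df.columns), MASTER_HEADER)
    specs: list[MedicineSpec] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            forms = tuple(DosageForm(f.strip()) for f in str(row.dosage_form).split("/"))
            specs.append(
                MedicineSpec(
                    code=str(row.medicine_code).strip(),
                    name=str(row.name).strip(),
                    strength_mg=float(row.strength_mg),
                    dosage_forms=forms,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    master_by_code(specs)  # enforce code uniqueness
    return specs


def _parse_row(row, known_codes: set[str], cfg: StudyConfig | None) -> PurchaseRecord:
    code = str(row.medicine_code).strip()
    if code not in known_codes:
        raise ValueError(f"unknown medicine code {code!r}")
    month = parse_month(str(row.purchase_date))
    if cfg is not None and not (cfg.start <= month <= cfg.end):
        raise ValueError(f"purchase_date {month} outside study window")
    try:
        category = Category(str(row.category).strip())
    except ValueError:
        raise ValueError(f"unknown category token {row.category!r}") from None
    qty_raw = str(row.quantity_units).strip()
    try:
        quantity = int(qty_raw)
    except ValueError:
        raise ValueError(f"quantity_units {qty_raw!r} is not an integer") from None
    try:
        price = float(str(row.unit_price).strip())
    except ValueError:
        raise ValueError(f"unit_price {row.unit_price!r} is not a number") from None
    try:
        ptype = ProcurementType(str(row.procurement_type).strip())
    except ValueError:
        raise ValueError(
            f"unknown procurement_type {row.procurement_type!r}"
        ) from None
    try:
        status = Status(str(row.status).strip())
    except ValueError:
        raise ValueError(f"unknown status {row.status!r}") from None
    return PurchaseRecord(
        medicine_code=code,
        purchase_date=month,
        category=category,
        entity_id=str(row.entity_id).strip(),
        quantity_units=quantity,
        unit_price=price,
        procurement_type=ptype,
        status=status,
    )


def read_purchases(
    path: str | Path,
    master: Iterable[MedicineSpec],
    *,
    config: StudyConfig | None = None,
    skip_invalid: bool = False,
) -> LedgerReadResult:
    """Read and validate a purchase-ledger CSV.

    Row order is preserved. In strict mode (default) any invalid row makes
    the whole read fail with :class:`LedgerValidationError`; with
    ``skip_invalid=True`` invalid rows are collected in ``.rejections``
    and logged instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(path, list(df.columns), PURCHASES_HEADER)
    known = {m.code for m in master}
    records: list[PurchaseRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(_parse_row(row, known, config))
        except ValueError as exc:
            issues.append(RowIssue(i, str(exc)))
    if issues and not skip_invalid:
        raise LedgerValidationError(issues, path)
    for issue in issues:
        log.warning("%s: skipped %s", path, issue)
    return LedgerReadResult(records=records, rejections=issues)


def write_purchases(records: Iterable[PurchaseRecord], path: str | Path) -> None:
    """Write records back to the ledger CSV schema (round-trip safe)."""
    rows = [
        {
            "medicine_code": r.medicine_code,
            "purchase_date": str(r.purchase_date),
            "category": r.category.value,
            "entity_id": r.entity_id,
            "quantity_units": r.quantity_units,
            "unit_price": repr(r.unit_price),
            "procurement_type": r.procurement_type.value,
            "status": r.status.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PURCHASES_HEADER).to_csv(path, index=False)


def filter_eligible(records: Iterable[PurchaseRecord]) -> list[PurchaseRecord]:
    """Keep only active purchases made through competitive bidding.

    Idempotent; relative order preserved.
    """
    return [
        r
        for r in records
        if r.status is Status.ACTIVE
        and r.procurement_type is ProcurementType.COMPETITIVE
    ]


def select_medicines(
    records: Iterable[PurchaseRecord], cfg: StudyConfig
) -> set[str]:
    """Codes purchased by the inclusion category in >= k distinct years.

    ``records`` should already be eligibility-filtered; the count is over
    distinct calendar years inside the study window with at least one
    qualifying purchase, not over purchase events.
    """
    years_by_code: dict[str, set[int]] = {}
    for r in records:
        if r.category is cfg.inclusion_category and cfg.start <= r.purchase_date <= cfg.end:
            years_by_code.setdefault(r.medicine_code, set()).add(r.year)
    return {
        code
        for code, years in years_by_code.items()
        if len(years) >= cfg.min_years_purchased
    }
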