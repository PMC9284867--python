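"""Lowest-price benchmark and avoidable-expenditure counterfactual.

For each medicine and year, the category paying the lowest WAP/mg sets
the benchmark. Every other category's counterfactual spend is what its
actual mg volume would have cost at the benchmark price:

    counterfactual = volume_mg * benchmark_wap
    avoidable      = actual_expenditure - counterfactual  (>= 0)

Avoidable expenditure divided by the benchmark WAP/mg gives the extra mg
— and, via the strength, the extra dispensing units — that could have
been bought for the same money. The benchmark category's own cell is not
applicable (NA) by construction, as are zero-volume strata.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .types import (
    CATEGORY_ORDER,
    Category,
    MedicineSpec,
    master_by_code,
    round_half_away,
)

__all__ = [
    "AvoidableEntry",
    "benchmark",
    "avoidable_entry",
    "additional_quantity",
    "avoidable_table",
    "additional_share",
]

log = logging.getLogger(__name__)

_CAT_RANK = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}


@dataclass(frozen=True)
class AvoidableEntry:
    """Avoidable expenditure of one medicine x year x category stratum."""

    medicine_code: str
    year: int
    category: Category
    actual_expenditure: float
    actual_wap: float
    benchmark_wap: float
    benchmark_category: Category
    counterfactual_expenditure: float
    avoidable_expenditure: float  # NaN when not applicable
    additional_mg: float
    additional_units: int

    @property
    def is_na(self) -> bool:
        return math.isnan(self.avoidable_expenditure)


def benchmark(waps_by_category: Mapping[Category | str, float]) -> tuple[float, Category]:
    """Lowest WAP/mg among categories with positive volume, with its label.

    Ties at the exact minimum are broken by the fixed category order
    ME < MH < MD < OI and logged.
    """
    items = [(Category(c), float(w)) for c, w in waps_by_category.items()]
    if not items:
        raise ValueError("no purchasing category with positive volume")
    low = min(w for _, w in items)
    tied = sorted((c for c, w in items if w == low), key=lambda c: _CAT_RANK[c.value])
    if len(tied) > 1:
        log.warning(
            "benchmark tie at WAP/mg=%g between %s; keeping %s",
            low, [c.value for c in tied], tied[0].value,
        )
    return low, tied[0]


def avoidable_entry(
    medicine_code: str,
    year: int,
    category: Category | str,
    volume_mg: float,
    expenditure: float,
    bench: tuple[float, Category],
    strength_mg: float,
) -> AvoidableEntry:
    """Build the avoidable-expenditure entry for one stratum."""
    category = Category(category)
    bench_wap, bench_cat = bench
    actual_wap = expenditure / volume_mg
    counterfactual = volume_mg * bench_wap
    if category == bench_cat:
        avoid, add_mg, add_units = float("nan"), float("nan"), 0
    else:
        # guard against -0.0 / 1-ulp noise when a non-benchmark category
        # pays the benchmark price to full precision
        avoid = max(0.0, expenditure - counterfactual)
        add_mg, add_units = additional_quantity(avoid, bench_wap, strength_mg)
    return AvoidableEntry(
        medicine_code=medicine_code,
        year=year,
        category=category,
        actual_expenditure=expenditure,
        actual_wap=actual_wap,
        benchmark_wap=bench_wap,
        benchmark_category=bench_cat,
        counterfactual_expenditure=counterfactual,
        avoidable_expenditure=avoid,
        additional_mg=add_mg,
        additional_units=add_units,
    )


def additional_quantity(
    avoidable_expenditure: float, benchmark_wap: float, strength_mg: float
) -> tuple[float, int]:
    """Extra mg and dispensing units purchasable with the avoided spend.

    Units are rounded half away from zero.
    """
    add_mg = avoidable_expenditure / benchmark_wap
    return add_mg, int(round_half_away(add_mg / strength_mg))


def avoidable_table(
    agg_myc: pd.DataFrame,
    master: Iterable[MedicineSpec] | Mapping[str, MedicineSpec],
) -> pd.DataFrame:
    """Avoidable expenditure for every medicine x year x category stratum.

    ``agg_myc`` is a deflated ``medicine_year_category`` aggregate. Rows
    where the stratum is its own benchmark carry NaN avoidable values.
    Columns: medicine_code, year, category, actual_expenditure, actual_wap,
    benchmark_wap, benchmark_category, counterfactual_expenditure,
    avoidable_expenditure, additional_mg, additional_units.
    """
    by_code = master if isinstance(master, Mapping) else master_by_code(master)
    entries: list[AvoidableEntry] = []
    for (code, year), sub in agg_myc.groupby(["medicine_code", "year"], sort=True):
        sub = sub[sub["volume_mg"] > 0]
        if sub.empty:
            continue
        bench = benchmark(dict(zip(sub["category"], sub["wap_per_mg"])))
        for _, row in sub.iterrows():
            entries.append(
                avoidable_entry(
                    code, int(year), row["category"], row["volume_mg"],
                    row["expenditure"], bench, by_code[code].strength_mg,
                )
            )
    return pd.DataFrame(
        [
            {
                "medicine_code": e.medicine_code,
                "year": e.year,
                "category": e.category.value,
                "actual_expenditure": e.actual_expenditure,
                "actual_wap": e.actual_wap,
                "benchmark_wap": e.benchmark_wap,
                "benchmark_category": e.benchmark_category.value,
                "counterfactual_expenditure": e.counterfactual_expenditure,
                "avoidable_expenditure": e.avoidable_expenditure,
                "additional_mg": e.additional_mg,
                "additional_units": e.additional_units,
            }
            for e in entries
        ],
        columns=[
            "medicine_code", "year", "category", "actual_expenditure",
            "actual_wap", "benchmark_wap", "benchmark_category",
            "counterfactual_expenditure", "avoidable_expenditure",
            "additional_mg", "additional_units",
        ],
    )


def additional_share(
    total_additional_units: float, total_volume_mg: float, strength_mg: float
) -> float:
    """Additional units as a percentage of total units purchased (2 dp)."""
    total_units = total_volume_mg / strength_mg
    return round_half_away(100.0 * total_additional_units / total_units, 2)
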