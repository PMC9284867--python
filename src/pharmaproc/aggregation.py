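"""Volume standardisation and per-stratum aggregation.

Purchase volumes are standardised to mg of active ingredient
(``quantity_units * strength_mg``), which makes medicines without a
defined daily dose comparable. For each stratum — medicine x purchaser
category, optionally split by calendar year — the module accumulates
total volume and (deflated) expenditure and derives the weighted average
price per mg:

    WAP/mg = total expenditure / total mg purchased

i.e. the purchase-volume-weighted mean of the per-mg prices paid.
Shares are computed on full-precision aggregates and rounded half away
from zero to two decimals only for display.
"""
from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .types import (
    CATEGORY_ORDER,
    MedicineSpec,
    PurchaseRecord,
    master_by_code,
    round_half_away,
)

__all__ = [
    "volume_mg",
    "aggregate",
    "collapse",
    "share",
    "table_volume",
    "table_spending",
]

Level = Literal["medicine_category", "medicine_year_category"]
Margin = Literal["by_medicine", "by_category", "grand_total"]
Measure = Literal["volume_mg", "expenditure"]

AGG_COLUMNS = ["medicine_code", "year", "category", "volume_mg", "expenditure", "wap_per_mg"]

_CAT_RANK = {c.value: i for i, c in enumerate(CATEGORY_ORDER)}


def volume_mg(record: PurchaseRecord, master: Iterable[MedicineSpec] | Mapping[str, MedicineSpec]) -> float:
    """Milligrams of active ingredient in one purchase event."""
    by_code = master if isinstance(master, Mapping) else master_by_code(master)
    return record.quantity_units * by_code[record.medicine_code].strength_mg


def aggregate(
    records: Iterable[PurchaseRecord],
    master: Iterable[MedicineSpec] | Mapping[str, MedicineSpec],
    level: Level = "medicine_year_category",
) -> pd.DataFrame:
    """Per-stratum totals and WAP/mg.

    Returns a frame with columns ``medicine_code, year, category,
    volume_mg, expenditure, wap_per_mg`` (``year`` is absent at the
    ``medicine_category`` level). Sums run over records in input order;
    empty strata are omitted.
    """
    by_code = master if isinstance(master, Mapping) else master_by_code(master)
    with_year = level == "medicine_year_category"
    sums: dict[tuple, list[float]] = {}
    for r in records:
        key = (r.medicine_code, r.year, r.category.value) if with_year else (
            r.medicine_code, r.category.value)
        acc = sums.setdefault(key, [0.0, 0.0])
        acc[0] += r.quantity_units * by_code[r.medicine_code].strength_mg
        acc[1] += r.quantity_units * r.unit_price
    rows = []
    for key in sorted(sums, key=lambda k: (k[:-1], _CAT_RANK[k[-1]])):
        vol, exp = sums[key]
        row = {"medicine_code": key[0], "category": key[-1],
               "volume_mg": vol, "expenditure": exp,
               "wap_per_mg": exp / vol if vol > 0 else float("nan")}
        if with_year:
            row["year"] = key[1]
        rows.append(row)
    cols = AGG_COLUMNS if with_year else [c for c in AGG_COLUMNS if c != "year"]
    return pd.DataFrame(rows, columns=cols)


def collapse(agg: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Pool strata over the keys in ``by``, recomputing WAP/mg."""
    out = agg.groupby(list(by), as_index=False, sort=True)[
        ["volume_mg", "expenditure"]
    ].sum()
    out["wap_per_mg"] = out["expenditure"] / out["volume_mg"]
    return out


def share(agg: pd.DataFrame, margin: Margin, measure: Measure = "expenditure") -> pd.DataFrame:
    """Percentage share of ``measure`` within the chosen margin.

    ``by_medicine`` normalises across each medicine's strata,
    ``by_category`` across each category's strata and ``grand_total``
    against the sum over all rows. Adds a ``share_pct`` column rounded
    half away from zero to 2 decimals.
    """
    out = agg.copy()
    if margin == "grand_total":
        denom = out[measure].sum()
        raw = 100.0 * out[measure] / denom
    else:
        key = "medicine_code" if margin == "by_medicine" else "category"
        denom = out.groupby(key)[measure].transform("sum")
        raw = 100.0 * out[measure] / denom
    out["share_pct"] = [round_half_away(v, 2) for v in raw]
    return out


def _wide(agg_mc: pd.DataFrame, measure: Measure) -> pd.DataFrame:
    shared = share(agg_mc, "by_medicine", measure)
    rows = []
    for code, sub in shared.groupby("medicine_code", sort=True):
        row: dict[str, object] = {"medicine_code": code}
        by_cat = {r["category"]: r for _, r in sub.iterrows()}
        for cat in _CAT_RANK:
            r = by_cat.get(cat)
            row[f"{cat}_n"] = r[measure] if r is not None else 0.0
            row[f"{cat}_pct"] = r["share_pct"] if r is not None else 0.0
        row["total"] = sub[measure].sum()
        rows.append(row)
    cols = ["medicine_code"]
    for cat in _CAT_RANK:
        cols += [f"{cat}_n", f"{cat}_pct"]
    return pd.DataFrame(rows, columns=cols + ["total"])


def table_volume(agg_mc: pd.DataFrame) -> pd.DataFrame:
    """Purchase quantities (mg) by medicine and purchaser category, with
    within-medicine percentage shares and a row total."""
    return _wide(agg_mc, "volume_mg")


def table_spending(agg_mc: pd.DataFrame) -> pd.DataFrame:
    """Total spending by medicine and purchaser category, with a final
    ``TOTAL`` row of category totals and their shares of overall spending."""
    wide = _wide(agg_mc, "expenditure")
    grand = wide["total"].sum()
    total_row: dict[str, object] = {"medicine_code": "TOTAL", "total": grand}
    for cat in _CAT_RANK:
        cat_total = wide[f"{cat}_n"].sum()
        total_row[f"{cat}_n"] = cat_total
        total_row[f"{cat}_pct"] = round_half_away(100.0 * cat_total / grand, 2)
    return pd.concat([wide, pd.DataFrame([total_row])], ignore_index=True)
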