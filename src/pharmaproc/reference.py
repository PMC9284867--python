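"""Packaged reference tables for the 2013-2019 Brazilian federal
procurement of breast-cancer antineoplastics, and their reconciliation.

The package ships, as plain CSVs, the published summary tables of the
study this pipeline operationalises: purchase volumes in mg (10
medicines x 4 purchaser categories), total spending in July-2019 R$,
and the per-year avoidable-expenditure / additional-units table with its
benchmark-category markers. They serve as an exact reconciliation
surface: re-running the pipeline's share and additional-quantity
formulas over the printed cells must reproduce the published totals and
percentages (the printed cells are individually rounded, so sums carry a
+/-2 slack).

Table 3 rows with ``year == "TOTAL"`` are the printed per-row total
cells; reconciliation of subtotals sums those, since the published
per-year cells accumulate one unit of rounding each.
"""
from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation
from .avoidable import additional_share
from .ingest import read_master
from .types import CATEGORY_ORDER, MedicineSpec

__all__ = [
    "load_master",
    "load_table1",
    "load_table2",
    "load_table3",
    "table_cells_long",
    "reconcile",
    "write_fixtures",
]

_FILES = ["master.csv", "table1_volume.csv", "table2_spending.csv", "table3_avoidable.csv"]


def _path(name: str):
    return resources.files("pharmaproc.refdata").joinpath(name)


def load_master() -> list[MedicineSpec]:
    """Master list of the ten study medicines."""
    with resources.as_file(_path("master.csv")) as p:
        return read_master(p)


def _load_wide(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p)


def load_table1() -> pd.DataFrame:
    """Published purchase volumes (mg) by medicine and category, wide layout."""
    return _load_wide("table1_volume.csv")


def load_table2() -> pd.DataFrame:
    """Published total spending (R$) by medicine and category, wide layout
    with a final TOTAL row."""
    return _load_wide("table2_spending.csv")


def load_table3() -> pd.DataFrame:
    """Published avoidable expenditure and additional units.

    Long layout: ``medicine_code, year, category, avoidable_expenditure,
    additional_units, benchmark_category``; ``year`` is a string and
    includes ``"TOTAL"`` rows (the printed row totals); NA cells are NaN.
    """
    with resources.as_file(_path("table3_avoidable.csv")) as p:
        df = pd.read_csv(p, dtype={"year": str}, na_values=["NA"], keep_default_na=False)
    for col in ("avoidable_expenditure", "additional_units"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def table_cells_long(wide: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Melt a wide reference table into an aggregate-like long frame.

    Returns ``medicine_code, category, <measure>`` rows, one per printed
    category cell (TOTAL rows excluded).
    """
    rows = []
    for _, r in wide.iterrows():
        if r["medicine_code"] == "TOTAL":
            continue
        for cat in CATEGORY_ORDER:
            rows.append(
                {
                    "medicine_code": r["medicine_code"],
                    "category": cat.value,
                    measure: float(r[f"{cat.value}_n"]),
                }
            )
    return pd.DataFrame(rows)


def reconcile() -> dict[str, float]:
    """Recompute the published headline figures from the shipped cells.

    Every value is produced by running the pipeline's own share /
    additional-quantity formulas over the reference-table cells.
    """
    master = {m.code: m for m in load_master()}
    t1, t2, t3 = load_table1(), load_table2(), load_table3()

    spend = table_cells_long(t2, "expenditure")
    total_spending = spend["expenditure"].sum()

    by_med = spend.groupby("medicine_code", as_index=False)["expenditure"].sum()
    med_share = aggregation.share(by_med, "grand_total", "expenditure")
    by_cat = spend.groupby("category", as_index=False)["expenditure"].sum()
    cat_share = aggregation.share(by_cat, "grand_total", "expenditure")

    vol = table_cells_long(t1, "volume_mg")
    vol_share = aggregation.share(vol, "by_medicine", "volume_mg")

    totals = t3[t3["year"] == "TOTAL"]
    ae_by_cat = totals.groupby("category")["avoidable_expenditure"].sum()
    units_by_cat = totals.groupby("category")["additional_units"].sum()
    ae_by_med = totals.groupby("medicine_code")["avoidable_expenditure"].sum()
    units_by_med = totals.groupby("medicine_code")["additional_units"].sum()

    def med_total_mg(code: str) -> float:
        return float(t1.loc[t1["medicine_code"] == code, "total"].iloc[0])

    def share_of_units(code: str) -> float:
        return additional_share(
            float(units_by_med[code]), med_total_mg(code), master[code].strength_mg
        )

    def pick(df: pd.DataFrame, col: str, **keys) -> float:
        mask = np.ones(len(df), dtype=bool)
        for k, v in keys.items():
            mask &= df[k] == v
        return float(df.loc[mask, col].iloc[0])

    return {
        "total_spending": float(total_spending),
        "trastuzumab_spending_share_pct": pick(
            med_share, "share_pct", medicine_code="TRA440"
        ),
        "other_institutions_spending_share_pct": pick(
            cat_share, "share_pct", category="OI"
        ),
        "trastuzumab_oi_volume_share_pct": pick(
            vol_share, "share_pct", medicine_code="TRA440", category="OI"
        ),
        "total_avoidable_expenditure": float(ae_by_cat.sum()),
        "defense_avoidable_expenditure": float(ae_by_cat["MD"]),
        "other_institutions_avoidable_expenditure": float(ae_by_cat["OI"]),
        "trastuzumab_avoidable_expenditure": float(ae_by_med["TRA440"]),
        "total_additional_units": float(units_by_cat.sum()),
        "education_additional_units": float(units_by_cat["ME"]),
        "tamoxifen_additional_units": float(units_by_med["TAM20"]),
        "anastrozole_additional_units": float(units_by_med["ANA1"]),
        "tamoxifen_additional_units_share_pct": share_of_units("TAM20"),
        "vinorelbine10_additional_units_share_pct": share_of_units("VIN10"),
    }


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Copy the packaged reference CSVs into ``out_dir`` (byte-identical)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _FILES:
        with resources.as_file(_path(name)) as src:
            dst = out / name
            shutil.copyfile(src, dst)
            written.append(dst)
    return written
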