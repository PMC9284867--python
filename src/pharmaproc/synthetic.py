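"""Seeded generator of procurement-registry-style purchase ledgers.

The generator emulates a multi-year, multi-buyer federal purchase ledger
with known structure, so that every pipeline stage can be tested against
closed-form ground truth without any external data:

* each purchaser category pays a planted price multiplier ``lambda_c``
  (the ``lambda = 1`` category is the benchmark by construction);
* nominal prices drift with a constant monthly inflation rate, and the
  matching price-index series is emitted alongside the ledger, so
  deflated per-mg prices are exactly ``base_price_per_mg * lambda_c``
  restated at the reference month;
* multiplicative log-normal noise with mean 1 models quote-to-quote price
  dispersion (prices are positive and right-skewed);
* a configurable fraction of rows is contaminated — flagged inactive or
  as non-competitive procurement — and must be removed by the
  eligibility filter.

Annual volumes are spread uniformly over months with the remainder going
to the earliest months, keeping the ledger deterministic for a fixed
seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .deflator import PriceIndexSeries
from .ingest import write_purchases
from .reference import write_fixtures  # re-exported: packaged published-table fixtures
from .types import (
    CATEGORY_ORDER,
    Category,
    DosageForm,
    MedicineSpec,
    Month,
    ProcurementType,
    PurchaseRecord,
    Status,
    month_offset,
    parse_month,
)

__all__ = [
    "MedicineSim",
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticDataset",
    "default_config",
    "generate",
    "write_dataset",
    "write_fixtures",
]


class MedicineSim(BaseModel):
    """A medicine in the simulation with its benchmark per-mg price."""

    code: str
    name: str
    strength_mg: float = Field(gt=0)
    dosage_form: str = "tablet"
    base_price_per_mg: float = Field(gt=0)

    def spec(self) -> MedicineSpec:
        forms = tuple(DosageForm(f) for f in self.dosage_form.split("/"))
        return MedicineSpec(self.code, self.name, self.strength_mg, forms)


class SimulationConfig(BaseModel):
    """Generator parameters; the seed fixes the entire ledger."""

    seed: int = 0
    window_start: str = "2013-01"
    window_end: str = "2019-12"
    reference_month: str = "2019-07"
    medicines: list[MedicineSim]
    category_multipliers: dict[Category, float]
    #: units per (medicine code -> category token -> calendar year)
    annual_units: dict[str, dict[Category, dict[int, int]]]
    monthly_inflation: float = 0.005
    #: inclusion rule the study pipeline will apply, echoed into the truth
    inclusion_category: Category = Category.HEALTH
    min_years_purchased: int = Field(default=5, ge=1)
    price_noise_cv: float = Field(default=0.1, ge=0)
    contamination_fraction: float = Field(default=0.15, ge=0, lt=1)
    events_per_month: int = Field(default=1, ge=1)
    index_base: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lam = self.category_multipliers
        if not lam:
            raise ValueError("category_multipliers must not be empty")
        if min(lam.values()) != 1.0:
            raise ValueError("minimum category multiplier must be exactly 1")
        if any(v < 1.0 for v in lam.values()):
            raise ValueError("category multipliers must be >= 1")
        codes = {m.code for m in self.medicines}
        for code, per_cat in self.annual_units.items():
            if code not in codes:
                raise ValueError(f"annual_units references unknown code {code!r}")
            for cat, by_year in per_cat.items():
                if cat not in lam:
                    raise ValueError(f"no multiplier for category {cat}")
                for year, units in by_year.items():
                    if units < 0:
                        raise ValueError(
                            f"negative volume for {code}/{cat}/{year}"
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


@dataclass
class SimulationTruth:
    """Closed-form noise-free expectations per medicine x year x category.

    ``frame`` columns: medicine_code, year, category, volume_mg,
    nominal_expenditure, expenditure (deflated), wap_per_mg,
    benchmark_category, avoidable_expenditure, additional_mg.
    """

    frame: pd.DataFrame
    n_eligible: int
    n_contaminated: int
    selected_codes: set[str]


@dataclass
class SyntheticDataset:
    records: list[PurchaseRecord]
    master: list[MedicineSpec]
    index: PriceIndexSeries
    truth: SimulationTruth
    config: SimulationConfig


def _split_even(total: int, parts: int) -> list[int]:
    """Uniform split with remainder assigned to the earliest parts."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _months_of(year: int, cfg: SimulationConfig) -> list[Month]:
    first = max(cfg.start, pd.Period(year=year, month=1, freq="M"))
    last = min(cfg.end, pd.Period(year=year, month=12, freq="M"))
    return list(pd.period_range(first, last, freq="M"))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-like default scenario.

    Ten medicines with per-mg base prices spanning four orders of
    magnitude (hormone-therapy tablets cents/mg, a monoclonal antibody
    tens of currency units/mg), the health ministry as benchmark buyer,
    the defense ministry paying the largest markup, and volume shares
    dominated by the education ministry's university hospitals.
    """
    panel = [
        ("ANA1", "Anastrozole", 1.0, "tablet", 1.20, 520_000),
        ("DOC40", "Docetaxel", 40.0, "ampoule", 2.00, 90_000),
        ("EXE25", "Exemestane", 25.0, "capsule", 0.70, 250_000),
        ("LET25", "Letrozole", 2.5, "tablet", 3.00, 200_000),
        ("PAC6", "Paclitaxel", 6.0, "ampoule", 0.45, 2_200_000),
        ("TAM20", "Tamoxifen", 20.0, "tablet", 0.05, 5_000_000),
        ("TRA440", "Trastuzumab", 440.0, "ampoule", 24.0, 9_500),
        ("VIN10", "Vinorelbine", 10.0, "ampoule/capsule", 3.00, 50_000),
        ("VIN20", "Vinorelbine", 20.0, "ampoule/capsule", 5.80, 18_000),
        ("VIN30", "Vinorelbine", 30.0, "ampoule/capsule", 5.70, 25_000),
    ]
    weights = {
        Category.EDUCATION: 0.45,
        Category.HEALTH: 0.30,
        Category.DEFENSE: 0.08,
        Category.OTHER: 0.17,
    }
    medicines = [
        MedicineSim(code=c, name=n, strength_mg=s, dosage_form=f, base_price_per_mg=p)
        for c, n, s, f, p, _ in panel
    ]
    cfg = SimulationConfig(
        seed=seed,
        medicines=medicines,
        category_multipliers={
            Category.HEALTH: 1.0,
            Category.EDUCATION: 1.1,
            Category.OTHER: 1.25,
            Category.DEFENSE: 1.5,
        },
        annual_units={
            c: {
                cat: {year: int(units * w) for year in range(2013, 2020)}
                for cat, w in weights.items()
            }
            for c, _, _, _, _, units in panel
        },
        **overrides,
    )
    return cfg


def _iter_strata(cfg: SimulationConfig) -> Iterator[tuple[MedicineSim, Category, int, int]]:
    lam_cats = [c for c in CATEGORY_ORDER if c in cfg.category_multipliers]
    for med in cfg.medicines:
        per_cat = cfg.annual_units.get(med.code, {})
        for cat in lam_cats:
            by_year = per_cat.get(cat, {})
            for year in cfg.years:
                units = int(by_year.get(year, 0))
                if units > 0:
                    yield med, cat, year, units


def _index_series(cfg: SimulationConfig) -> PriceIndexSeries:
    last = max(cfg.end, cfg.reference)
    months = pd.period_range(cfg.start, last, freq="M")
    return PriceIndexSeries(
        {
            m: cfg.index_base * (1.0 + cfg.monthly_inflation) ** month_offset(m, cfg.start)
            for m in months
        }
    )


def generate(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a ledger, its index series, master list and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    cv = cfg.price_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    def unit_price(med: MedicineSim, cat: Category, month: Month) -> float:
        drift = (1.0 + cfg.monthly_inflation) ** month_offset(month, cfg.start)
        price = med.strength_mg * med.base_price_per_mg * cfg.category_multipliers[cat] * drift
        if sigma > 0:
            price *= float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
        return price

    eligible: list[PurchaseRecord] = []
    truth_rows = []
    lam_min = min(cfg.category_multipliers.values())
    bench_cat = next(
        c for c in CATEGORY_ORDER
        if cfg.category_multipliers.get(c) == lam_min
    )
    ref_drift = (1.0 + cfg.monthly_inflation) ** month_offset(cfg.reference, cfg.start)

    for med, cat, year, units in _iter_strata(cfg):
        months = _months_of(year, cfg)
        nominal = 0.0
        for month, month_units in zip(months, _split_even(units, len(months))):
            if month_units == 0:
                continue
            for q in _split_even(month_units, cfg.events_per_month):
                if q == 0:
                    continue
                eligible.append(
                    PurchaseRecord(
                        medicine_code=med.code,
                        purchase_date=month,
                        category=cat,
                        entity_id=f"{cat.value}-001",
                        quantity_units=q,
                        unit_price=unit_price(med, cat, month),
                        procurement_type=ProcurementType.COMPETITIVE,
                        status=Status.ACTIVE,
                    )
                )
            drift = (1.0 + cfg.monthly_inflation) ** month_offset(month, cfg.start)
            nominal += (
                month_units * med.strength_mg * med.base_price_per_mg
                * cfg.category_multipliers[cat] * drift
            )
        lam = cfg.category_multipliers[cat]
        wap = med.base_price_per_mg * lam * ref_drift
        volume = units * med.strength_mg
        bench_wap = med.base_price_per_mg * lam_min * ref_drift
        avoid = float("nan") if cat == bench_cat else volume * (wap - bench_wap)
        truth_rows.append(
            {
                "medicine_code": med.code,
                "year": year,
                "category": cat.value,
                "volume_mg": volume,
                "nominal_expenditure": nominal,
                "expenditure": volume * wap,
                "wap_per_mg": wap,
                "benchmark_category": bench_cat.value,
                "avoidable_expenditure": avoid,
                "additional_mg": 0.0 if cat == bench_cat else avoid / bench_wap,
            }
        )

    n_eligible = len(eligible)
    f = cfg.contamination_fraction
    n_contam = int(round(f / (1.0 - f) * n_eligible)) if f > 0 else 0
    contaminated: list[PurchaseRecord] = []
    if n_contam:
        meds = cfg.medicines
        cats = [c for c in CATEGORY_ORDER if c in cfg.category_multipliers]
        all_months = list(pd.period_range(cfg.start, cfg.end, freq="M"))
        for i in range(n_contam):
            med = meds[int(rng.integers(len(meds)))]
            cat = cats[int(rng.integers(len(cats)))]
            month = all_months[int(rng.integers(len(all_months)))]
            qty = int(rng.integers(1, 200))
            if i % 2 == 0:
                status, ptype = Status.INACTIVE, ProcurementType.COMPETITIVE
            else:
                status = Status.ACTIVE
                ptype = (
                    ProcurementType.WAIVER if i % 4 == 1
                    else ProcurementType.NOT_REQUIRED
                )
            contaminated.append(
                PurchaseRecord(
                    medicine_code=med.code,
                    purchase_date=month,
                    category=cat,
                    entity_id=f"{cat.value}-X{i % 7:02d}",
                    quantity_units=qty,
                    unit_price=unit_price(med, cat, month),
                    procurement_type=ptype,
                    status=status,
                )
            )

    records = eligible + contaminated
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    truth_frame = pd.DataFrame(
        truth_rows,
        columns=[
            "medicine_code", "year", "category", "volume_mg",
            "nominal_expenditure", "expenditure", "wap_per_mg",
            "benchmark_category", "avoidable_expenditure", "additional_mg",
        ],
    )
    selected = {
        code
        for code, sub in truth_frame[
            truth_frame["category"] == cfg.inclusion_category.value
        ].groupby("medicine_code")
        if sub["year"].nunique() >= cfg.min_years_purchased
    }
    truth = SimulationTruth(
        frame=truth_frame,
        n_eligible=n_eligible,
        n_contaminated=n_contam,
        selected_codes=selected,
    )
    return SyntheticDataset(
        records=records,
        master=[m.spec() for m in cfg.medicines],
        index=_index_series(cfg),
        truth=truth,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ledger, master, index and truth CSVs; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "purchases": out / "purchases.csv",
        "master": out / "master.csv",
        "index": out / "index.csv",
        "truth": out / "truth.csv",
    }
    write_purchases(ds.records, paths["purchases"])
    pd.DataFrame(
        {
            "medicine_code": [m.code for m in ds.master],
            "name": [m.name for m in ds.master],
            "strength_mg": [repr(m.strength_mg) for m in ds.master],
            "dosage_form": ["/".join(f.value for f in m.dosage_forms) for m in ds.master],
        }
    ).to_csv(paths["master"], index=False)
    ds.index.to_csv(paths["index"])
    ds.truth.frame.to_csv(paths["truth"], index=False)
    return paths
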