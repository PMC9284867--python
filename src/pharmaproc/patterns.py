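"""Volume-price pattern classification.

Annual purchase volume and WAP/mg trajectories fall into two qualitative
regimes: a *market* pattern, where volume and price move inversely (the
expected demand response), and an *inelastic* pattern, where volume does
not appear to influence the price paid. The classifier makes that
dichotomy operational with a Spearman rank correlation rho between
annual volume (mg) and annual WAP/mg:

* ``market`` when rho <= market_threshold (default -0.5),
* ``inelastic`` when |rho| < inelastic_threshold (default 0.3),
* ``indeterminate`` otherwise,
* ``insufficient_data`` with fewer than ``min_years`` usable years.

Rank correlation makes the label invariant to positive rescaling of
either axis and to the ordering of years. A zero-variance WAP series is
assigned rho = 0 — literal price constancy is the paradigm of
inelasticity.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import Category

__all__ = ["PatternResult", "classify_pattern", "patterns_table"]


@dataclass(frozen=True)
class PatternResult:
    medicine_code: str
    category: Category | None
    rho: float
    n_years: int
    label: str  # market | inelastic | indeterminate | insufficient_data


def classify_pattern(
    series: Sequence[tuple[int, float, float]],
    *,
    market_threshold: float = -0.5,
    inelastic_threshold: float = 0.3,
    min_years: int = 4,
    medicine_code: str = "",
    category: Category | None = None,
) -> PatternResult:
    """Classify one (year, volume_mg, wap_per_mg) trajectory.

    Years with zero volume are dropped before correlating; rho is computed
    on the paired annual values, so permuting the series does not change it.
    """
    usable = [(v, w) for _, v, w in series if v > 0]
    n = len(usable)
    if n < min_years:
        return PatternResult(medicine_code, category, 0.0, n, "insufficient_data")
    vol = np.array([v for v, _ in usable], dtype=float)
    wap = np.array([w for _, w in usable], dtype=float)
    if np.ptp(vol) == 0.0 or np.ptp(wap) == 0.0:
        rho = 0.0  # zero-variance convention
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(stats.spearmanr(vol, wap).statistic)
        if math.isnan(rho):
            rho = 0.0
    if rho <= market_threshold:
        label = "market"
    elif abs(rho) < inelastic_threshold:
        label = "inelastic"
    else:
        label = "indeterminate"
    return PatternResult(medicine_code, category, rho, n, label)


def patterns_table(
    agg_myc: pd.DataFrame,
    *,
    market_threshold: float = -0.5,
    inelastic_threshold: float = 0.3,
    min_years: int = 4,
) -> pd.DataFrame:
    """Classify every medicine x category trajectory of an annual aggregate.

    ``agg_myc`` is a ``medicine_year_category`` aggregate frame. Returns
    columns ``medicine_code, category, rho, n_years, label``.
    """
    rows = []
    for (code, cat), sub in agg_myc.groupby(["medicine_code", "category"], sort=True):
        sub = sub.sort_values("year")
        res = classify_pattern(
            list(zip(sub["year"], sub["volume_mg"], sub["wap_per_mg"])),
            market_threshold=market_threshold,
            inelastic_threshold=inelastic_threshold,
            min_years=min_years,
            medicine_code=code,
            category=Category(cat),
        )
        rows.append(
            {"medicine_code": code, "category": cat, "rho": res.rho,
             "n_years": res.n_years, "label": res.label}
        )
    return pd.DataFrame(rows, columns=["medicine_code", "category", "rho", "n_years", "label"])
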