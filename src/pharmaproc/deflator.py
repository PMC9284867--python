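"""Inflation adjustment of nominal prices with a monthly price-index series.

A nominal price observed in month *m* is restated in reference-month
currency as ``nominal * idx[ref] / idx[m]``. The index is a consumer
price index (IPCA in the Brazilian case) supplied as a monthly CSV
``month,index_value``; when only annual variation factors are available,
:meth:`PriceIndexSeries.from_annual_factors` expands them into a
step-wise monthly series (constant within each calendar year).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .types import Month, PurchaseRecord, parse_month

__all__ = ["IndexCoverageError", "PriceIndexSeries", "adjust_price", "adjust_records"]


class IndexCoverageError(KeyError):
    """The index series does not cover a month needed for adjustment."""

    def __init__(self, month: Month):
        self.month = month
        super().__init__(f"price index does not cover month {month}")


class PriceIndexSeries:
    """Contiguous monthly price-index series with strictly positive values."""

    def __init__(self, entries: Mapping[str | Month, float]):
        items = sorted((parse_month(m), float(v)) for m, v in entries.items())
        if not items:
            raise ValueError("empty price index series")
        months = [m for m, _ in items]
        for prev, cur in zip(months, months[1:]):
            if (cur - prev).n != 1:
                raise ValueError(
                    f"price index months not contiguous: gap between {prev} and {cur}"
                )
        for m, v in items:
            if v <= 0:
                raise ValueError(f"index value for {m} must be > 0, got {v}")
        self._values = dict(items)
        self.start: Month = months[0]
        self.end: Month = months[-1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceIndexSeries":
        # dtype=str + Python float(): exact round-trip of repr-formatted values
        df = pd.read_csv(path, dtype=str)
        if list(df.columns) != ["month", "index_value"]:
            raise ValueError(
                f"{path}: malformed header {list(df.columns)!r}, "
                "expected ['month', 'index_value']"
            )
        return cls({m: float(v) for m, v in zip(df["month"], df["index_value"])})

    @classmethod
    def from_annual_factors(
        cls, annual_factors: Mapping[int, float], *, base_value: float = 100.0
    ) -> "PriceIndexSeries":
        """Expand annual variation factors into a step-wise monthly series.

        ``annual_factors[year]`` is the multiplicative variation applied at
        the start of ``year`` (e.g. ``1.043`` for 4.3% annual inflation);
        the first listed year takes the base value. The index is constant
        within each calendar year.
        """
        entries: dict[Month, float] = {}
        value = float(base_value)
        first = True
        for year in sorted(annual_factors):
            if not first:
                value *= float(annual_factors[year])
            first = False
            for month in range(1, 13):
                entries[pd.Period(year=year, month=month, freq="M")] = value
        return cls(entries)

    def __contains__(self, month: str | Month) -> bool:
        return parse_month(month) in self._values

    def __getitem__(self, month: str | Month) -> float:
        m = parse_month(month)
        try:
            return self._values[m]
        except KeyError:
            raise IndexCoverageError(m) from None

    def months(self) -> list[Month]:
        return sorted(self._values)

    def factor(self, month: str | Month, ref: str | Month) -> float:
        """Multiplier restating a month-``month`` price in ``ref`` currency."""
        return self[ref] / self[month]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"month": [str(m) for m in self.months()],
             "index_value": [repr(self._values[m]) for m in self.months()]}
        ).to_csv(path, index=False)


def adjust_price(
    nominal: float, month: str | Month, ref: str | Month, idx: PriceIndexSeries
) -> float:
    """Restate a nominal price observed in ``month`` in ``ref`` currency."""
    return nominal * idx.factor(month, ref)


def adjust_records(
    records: Iterable[PurchaseRecord], ref: str | Month, idx: PriceIndexSeries
) -> list[PurchaseRecord]:
    """Deflate every record's unit price to the reference month.

    Quantities are untouched; raises :class:`IndexCoverageError` naming the
    first uncovered purchase month.
    """
    ref = parse_month(ref)
    return [
        r.with_price(adjust_price(r.unit_price, r.purchase_date, ref, idx))
        for r in records
    ]
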