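"""mg standardisation, stratum aggregation, WAP/mg and share tables."""
from __future__ import annotations

import random

import pytest

from pharmaproc import (
    Category,
    aggregate,
    collapse,
    round_half_away,
    share,
    table_spending,
    table_volume,
    volume_mg,
)

from conftest import make_record


class TestVolumeMg:
    def test_tablet_product(self, master):
        # 10 units of a 10 mg tablet
        assert volume_mg(make_record("A10", quantity=10), master) == 100.0

    def test_single_high_strength_unit(self, master):
        assert volume_mg(make_record("C440", quantity=1), master) == 440.0


class TestAggregate:
    def test_single_record_stratum(self, master):
        # 10 units x 10 mg at 2.00/unit -> 100 mg, 20.00, WAP/mg 0.20
        agg = aggregate([make_record("A10", quantity=10, price=2.0)], master)
        row = agg.iloc[0]
        assert row["volume_mg"] == 100.0
        assert row["expenditure"] == 20.0
        assert row["wap_per_mg"] == pytest.approx(0.2)
        assert row["year"] == 2015 and row["category"] == "MH"

    def test_equal_volumes_average_prices(self, master):
        # equal mg at unit prices p and 3p -> WAP/mg = 2p / strength
        p = 1.4
        agg = aggregate(
            [make_record("A10", price=p), make_record("A10", price=3 * p)], master
        )
        assert agg.iloc[0]["wap_per_mg"] == pytest.approx(2 * p / 10.0)

    def test_strata_split_by_year_and_category(self, master):
        records = [
            make_record("A10", "2014-01", Category.HEALTH),
            make_record("A10", "2015-01", Category.HEALTH),
            make_record("A10", "2015-01", Category.DEFENSE),
        ]
        agg = aggregate(records, master)
        assert len(agg) == 3
        assert set(zip(agg["year"], agg["category"])) == {
            (2014, "MH"), (2015, "MH"), (2015, "MD")}

    def test_conservation_of_expenditure(self, master):
        rng = random.Random(7)
        records = [
            make_record(
                rng.choice(["A10", "B25", "C440"]),
                f"201{rng.randint(3, 9)}-{rng.randint(1, 12):02d}",
                rng.choice(list(Category)),
                rng.randint(1, 500),
                rng.uniform(0.1, 90.0),
            )
            for _ in range(300)
        ]
        agg = aggregate(records, master)
        assert agg["expenditure"].sum() == pytest.approx(
            sum(r.quantity_units * r.unit_price for r in records), rel=1e-12
        )

    def test_matches_naive_loop_oracle(self, master):
        """On small ledgers the aggregate equals a per-record loop bit-for-bit."""
        rng = random.Random(42)
        records = [
            make_record(
                rng.choice(["A10", "B25"]),
                f"2015-{rng.randint(1, 12):02d}",
                rng.choice([Category.HEALTH, Category.OTHER]),
                rng.randint(1, 40),
                rng.uniform(0.5, 20.0),
            )
            for _ in range(50)
        ]
        agg = aggregate(records, master)
        strength = {"A10": 10.0, "B25": 25.0}
        for _, row in agg.iterrows():
            vol = 0.0
            exp = 0.0
            for r in records:  # independent naive accumulation in ledger order
                if (r.medicine_code, r.year, r.category.value) == (
                    row["medicine_code"], row["year"], row["category"]
                ):
                    vol += r.quantity_units * strength[r.medicine_code]
                    exp += r.quantity_units * r.unit_price
            assert row["volume_mg"] == vol
            assert row["expenditure"] == exp
            assert row["wap_per_mg"] == exp / vol

    def test_pooled_wap_within_substrata_bounds(self, master):
        rng = random.Random(3)
        records = [
            make_record("B25", f"201{y}-01", cat, rng.randint(1, 30), rng.uniform(1, 9))
            for y in range(3, 10)
            for cat in Category
        ]
        agg = aggregate(records, master)
        pooled = collapse(agg, ["medicine_code"])
        assert len(pooled) == 1
        wap = pooled.iloc[0]["wap_per_mg"]
        assert agg["wap_per_mg"].min() <= wap <= agg["wap_per_mg"].max()


class TestShare:
    def test_single_stratum_margin_is_100(self, master):
        agg = aggregate([make_record("A10")], master)
        out = share(agg, "by_medicine", "expenditure")
        assert out.iloc[0]["share_pct"] == 100.00

    @pytest.mark.parametrize("margin, measure", [
        ("by_medicine", "volume_mg"),
        ("by_category", "expenditure"),
        ("grand_total", "expenditure"),
    ])
    def test_margins_sum_to_100(self, master, margin, measure):
        rng = random.Random(11)
        records = [
            make_record(code, f"2016-{rng.randint(1, 12):02d}", cat,
                        rng.randint(1, 99), rng.uniform(0.2, 40))
            for code in ("A10", "B25", "C440")
            for cat in Category
        ]
        out = share(aggregate(records, master, "medicine_category"), margin, measure)
        if margin == "grand_total":
            groups = [out]
        else:
            key = "medicine_code" if margin == "by_medicine" else "category"
            groups = [g for _, g in out.groupby(key)]
        for g in groups:
            assert g["share_pct"].sum() == pytest.approx(100.0, abs=0.02)


class TestRounding:
    @pytest.mark.parametrize("x, nd, expected", [
        (2.675, 2, 2.68),      # half away from zero, no float-repr trap
        (0.125, 2, 0.13),
        (-0.125, 2, -0.13),
        (2.5, 0, 3.0),
        (72.676, 2, 72.68),
    ])
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestWideTables:
    def test_volume_table_layout_and_total(self, master):
        records = [
            make_record("A10", "2015-01", Category.EDUCATION, 30, 1.0),
            make_record("A10", "2015-02", Category.HEALTH, 10, 1.0),
        ]
        t1 = table_volume(aggregate(records, master, "medicine_category"))
        row = t1.iloc[0]
        assert row["ME_n"] == 300.0 and row["MH_n"] == 100.0
        assert row["ME_pct"] == 75.0 and row["MH_pct"] == 25.0
        assert row["total"] == 400.0

    def test_spending_table_has_grand_total_row(self, master):
        records = [
            make_record("A10", "2015-01", Category.EDUCATION, 10, 3.0),
            make_record("B25", "2015-01", Category.OTHER, 10, 1.0),
        ]
        t2 = table_spending(aggregate(records, master, "medicine_category"))
        total = t2[t2["medicine_code"] == "TOTAL"].iloc[0]
        assert total["total"] == pytest.approx(40.0)
        assert total["ME_pct"] == 75.0 and total["OI_pct"] == 25.0
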