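"""Ledger parsing, validation and the eligibility / inclusion filters."""
from __future__ import annotations

import pytest

from pharmaproc import (
    Category,
    LedgerValidationError,
    ProcurementType,
    Status,
    StudyConfig,
    filter_eligible,
    read_purchases,
    select_medicines,
    write_purchases,
)

from conftest import make_record

HEADER = "medicine_code,purchase_date,category,entity_id,quantity_units,unit_price,procurement_type,status\n"


def _ledger(tmp_path, rows: list[str]):
    path = tmp_path / "purchases.csv"
    path.write_text(HEADER + "".join(r + "\n" for r in rows))
    return path


class TestReadPurchases:
    def test_well_formed_rows_parse_in_order(self, tmp_path, master):
        path = _ledger(tmp_path, [
            "A10,2015-06,MH,E1,10,2.0,competitive,active",
            "B25,2014-02,ME,E2,3,15.5,waiver,active",
            "C440,2019-12,OI,E3,1,9000,competitive,inactive",
        ])
        result = read_purchases(path, master)
        assert [r.medicine_code for r in result] == ["A10", "B25", "C440"]
        assert result.records[1].unit_price == 15.5
        assert result.records[2].purchase_date.year == 2019
        assert not result.rejections

    def test_zero_quantity_row_fails_validation(self, tmp_path, master):
        path = _ledger(tmp_path, ["A10,2015-06,MH,E1,0,2.0,competitive,active"])
        with pytest.raises(LedgerValidationError, match="quantity"):
            read_purchases(path, master)

    def test_unknown_code_skipped_with_flag(self, tmp_path, master):
        rows = ["A10,2015-06,MH,E1,10,2.0,competitive,active"] * 2
        rows.insert(1, "ZZZ,2015-06,MH,E1,10,2.0,competitive,active")
        rows += ["B25,2015-07,MD,E4,5,8.0,competitive,active"] * 2
        result = read_purchases(_ledger(tmp_path, rows), master, skip_invalid=True)
        assert len(result.records) == 4
        assert len(result.rejections) == 1
        assert "ZZZ" in result.rejections[0].message

    @pytest.mark.parametrize("bad_row, fragment", [
        ("A10,2015-6-01,MH,E1,1,2.0,competitive,active", "month"),
        ("A10,2015-06,XX,E1,1,2.0,competitive,active", "category"),
        ("A10,2015-06,MH,E1,1,-2.0,competitive,active", "unit_price"),
        ("A10,2015-06,MH,E1,1,2.0,direct,active", "procurement_type"),
        ("A10,2015-06,MH,E1,1,2.0,competitive,pending", "status"),
    ])
    def test_invalid_fields_rejected(self, tmp_path, master, bad_row, fragment):
        with pytest.raises(LedgerValidationError, match=fragment):
            read_purchases(_ledger(tmp_path, [bad_row]), master)

    def test_malformed_header_rejected(self, tmp_path, master):
        path = tmp_path / "bad.csv"
        path.write_text("code,date\nA10,2015-06\n")
        with pytest.raises(ValueError, match="header"):
            read_purchases(path, master)

    def test_missing_file(self, master):
        with pytest.raises(FileNotFoundError):
            read_purchases("no/such/file.csv", master)

    def test_out_of_window_date_rejected(self, tmp_path, master):
        cfg = StudyConfig(window_start="2013-01", window_end="2019-12")
        path = _ledger(tmp_path, ["A10,2012-12,MH,E1,1,2.0,competitive,active"])
        with pytest.raises(LedgerValidationError, match="window"):
            read_purchases(path, master, config=cfg)

    def test_roundtrip_identity(self, tmp_path, master):
        records = [
            make_record("A10", "2013-01", Category.EDUCATION, 7, 1.25),
            make_record("C440", "2019-07", Category.OTHER, 2, 8123.4567,
                        ProcurementType.WAIVER, Status.INACTIVE),
        ]
        path = tmp_path / "rt.csv"
        write_purchases(records, path)
        back = read_purchases(path, master).records
        assert back == records


class TestFilterEligible:
    def test_only_active_competitive_survive(self):
        records = [
            make_record(status=Status.ACTIVE, procurement=ProcurementType.COMPETITIVE),
            make_record(status=Status.ACTIVE, procurement=ProcurementType.WAIVER),
            make_record(status=Status.INACTIVE, procurement=ProcurementType.COMPETITIVE),
            make_record(status=Status.ACTIVE, procurement=ProcurementType.NOT_REQUIRED),
        ]
        assert filter_eligible(records) == [records[0]]

    def test_identity_on_clean_ledger(self):
        records = [make_record(month=f"2015-{m:02d}") for m in range(1, 7)]
        assert filter_eligible(records) == records

    def test_idempotent(self):
        records = [
            make_record(status=s, procurement=p)
            for s in Status for p in ProcurementType
        ]
        once = filter_eligible(records)
        assert filter_eligible(once) == once


class TestSelectMedicines:
    cfg = StudyConfig(min_years_purchased=5)

    @staticmethod
    def _records(code: str, years: list[int], category=Category.HEALTH):
        return [make_record(code, f"{y}-03", category) for y in years]

    def test_exactly_k_years_selected(self):
        records = self._records("A10", [2013, 2014, 2015, 2016, 2017])
        assert select_medicines(records, self.cfg) == {"A10"}

    def test_below_threshold_excluded(self):
        records = self._records("A10", [2013, 2014, 2015, 2016])
        assert select_medicines(records, self.cfg) == set()

    def test_counts_distinct_years_not_purchases(self):
        # many purchases within few years must not qualify
        records = self._records("A10", [2013] * 10 + [2014] * 10)
        assert select_medicines(records, self.cfg) == set()

    def test_other_categories_do_not_drive_inclusion(self):
        records = self._records("A10", list(range(2013, 2020)), Category.DEFENSE)
        assert select_medicines(records, self.cfg) == set()

    def test_monotone_in_k(self):
        records = (
            self._records("A10", [2013, 2014, 2015, 2016, 2017, 2018])
            + self._records("B25", [2013, 2014, 2015])
            + self._records("C440", list(range(2013, 2020)))
        )
        previous = None
        for k in range(1, 8):
            cfg = StudyConfig(min_years_purchased=k)
            selected = select_medicines(records, cfg)
            if previous is not None:
                assert selected <= previous
            previous = selected
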