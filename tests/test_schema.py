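import pytest
from hypothesis import given, strategies as st

from pivasqc.schema import (
    DEFAULT_AUDIT_RULES,
    Period,
    SubmissionParseError,
    Vocabulary,
    aggregate_year,
    audit_submission,
    parse_submission,
    read_submissions_csv,
    serialize_submission,
    write_submissions_csv,
)

from conftest import base_record, make_submission


class TestSchemaShape:
    def test_exactly_67_items(self, schema):
        assert len(schema.items) == 67

    def test_aspect_partition(self, schema):
        assert schema.aspect_sizes == {"A": 12, "B": 12, "C": 10, "D": 19, "E": 11, "F": 3}

    def test_item_ids_follow_aspect_numbering(self, schema):
        for item_id, item in schema.items.items():
            assert item_id[0] == item.aspect
            assert 1 <= int(item_id[1:]) <= 19

    def test_contact_items_optional_rest_required(self, schema):
        optional = {"A03", "A04", "A05", "A06", "A07", "A10", "A11"}
        assert {i for i, it in schema.items.items() if not it.required} == optional

    def test_vocabulary_thresholds_present(self, schema):
        assert schema.vocabularies["director_title"].threshold == "supervising pharmacist"
        assert schema.vocabularies["degree"].threshold == "bachelor"

    def test_vocabulary_rejects_duplicates(self):
        with pytest.raises(ValueError):
            Vocabulary("x", ("a", "a"))


class TestPeriod:
    def test_quarterly_and_annual(self):
        assert str(Period(2021, 3)) == "2021Q3"
        assert str(Period(2021, 0)) == "2021"
        assert Period.parse("2021Q3") == Period(2021, 3)
        assert Period.parse("2021") == Period(2021, 0)

    def test_invalid_quarter(self):
        with pytest.raises(ValueError):
            Period(2021, 5)


class TestParse:
    def test_numeric_coercion(self, schema, record):
        sub = parse_submission(record, schema)
        assert sub.items["B01"] == 350.0
        assert sub.items["D05"] == 600
        assert sub.items["D15"] == 200
        assert sub.items["F02"] is True

    def test_full_record_has_67_items(self, schema, record):
        sub = parse_submission(record, schema)
        assert len(sub.items) == 67

    def test_type_mismatch_names_item(self, schema, record):
        record["B01"] = "large"
        with pytest.raises(SubmissionParseError, match="B01 expects float"):
            parse_submission(record, schema)

    def test_unknown_key_rejected_or_ignored(self, schema, record):
        record["Z99"] = "1"
        with pytest.raises(SubmissionParseError, match="Z99"):
            parse_submission(record, schema)
        sub = parse_submission(record, schema, on_unknown="warn")
        assert "Z99" not in sub.items

    def test_missing_period_or_facility(self, schema, record):
        del record["year"]
        with pytest.raises(SubmissionParseError, match="period"):
            parse_submission(record, schema)

    def test_empty_values_treated_as_absent(self, schema, record):
        record["D04"] = ""
        sub = parse_submission(record, schema)
        assert "D04" not in sub.items

    def test_category_level_validated(self, schema, record):
        record["C09"] = "astronaut"
        with pytest.raises(SubmissionParseError, match="C09"):
            parse_submission(record, schema)

    def test_round_trip_identity(self, schema, record):
        sub = parse_submission(record, schema)
        again = parse_submission(serialize_submission(sub, schema), schema)
        assert again.items == sub.items
        assert again.facility_id == sub.facility_id
        assert again.period == sub.period


class TestAudit:
    def test_consistent_submission_passes_clean(self, schema, submission):
        report = audit_submission(submission, schema=schema)
        assert report.status == "pass"
        assert report.findings == []

    def test_unreasonable_exceeding_total_fails(self, schema):
        sub = make_submission(schema, D06=50, D14=40, D16=100.0)
        report = audit_submission(sub, schema=schema)
        assert report.status == "fail"
        assert any(f.item_id == "D06" and f.severity == "error" for f in report.findings)

    def test_beds_ordering(self, schema):
        sub = make_submission(schema, B02=500, B10=600)
        report = audit_submission(sub, schema=schema)
        assert any("B02 > B10" in f.message for f in report.findings)

    def test_modified_exceeding_unreasonable(self, schema):
        sub = make_submission(schema, D17=600)
        report = audit_submission(sub, schema=schema)
        assert any(f.item_id == "D17" and f.severity == "error" for f in report.findings)

    def test_percentage_range(self, schema):
        sub = make_submission(schema, E02=105.0)
        report = audit_submission(sub, schema=schema)
        assert any(f.item_id == "E02" and f.rule_id == "range" for f in report.findings)

    def test_negative_count(self, schema):
        sub = make_submission(schema, D08=-1)
        assert not audit_submission(sub, schema=schema).passed

    def test_missing_required_item_is_error(self, schema, record):
        del record["D04"]
        sub = parse_submission(record, schema)
        report = audit_submission(sub, schema=schema)
        assert any(f.item_id == "D04" and f.rule_id == "completeness" for f in report.findings)

    def test_d16_mismatch_is_warning_only(self, schema):
        sub = make_submission(schema, D16=50.0)  # implied is ~1.37%
        report = audit_submission(sub, schema=schema)
        assert report.status == "pass"
        assert any(f.item_id == "D16" and f.severity == "warning" for f in report.findings)

    def test_trained_exceeding_staff_warns(self, schema):
        sub = make_submission(schema, C03=99)
        report = audit_submission(sub, schema=schema)
        assert report.status == "pass"
        assert any(f.item_id == "C03" and f.severity == "warning" for f in report.findings)

    def test_idempotent_and_order_independent(self, schema):
        sub = make_submission(schema, D06=50, D14=40, E02=105.0)
        r1 = audit_submission(sub, DEFAULT_AUDIT_RULES, schema)
        r2 = audit_submission(sub, tuple(reversed(DEFAULT_AUDIT_RULES)), schema)
        r3 = audit_submission(sub, DEFAULT_AUDIT_RULES, schema)
        assert r1.findings == r2.findings == r3.findings

    @given(st.integers(0, 1000), st.integers(0, 1000))
    def test_status_fail_iff_error_finding(self, d06, d14):
        from pivasqc.schema import default_schema

        schema = default_schema()
        sub = make_submission(schema, D06=d06, D14=d14, D17=0,
                              D16=round(100 * d06 / d14, 2) if d14 else 0.0)
        report = audit_submission(sub, schema=schema)
        assert (report.status == "fail") == bool(report.errors())


class TestAggregateYear:
    def test_flows_sum_stocks_last_rates_average(self, schema):
        quarters = [make_submission(schema, quarter=q) for q in (1, 2, 3, 4)]
        year = aggregate_year(quarters, schema)
        assert year.period == Period(2021, 0)
        assert year.items["D01"] == 4 * 72800   # flow: summed
        assert year.items["D05"] == 600         # daily average: averaged
        assert year.items["B02"] == 500         # stock: last
        assert year.items["E01"] == 52
        assert year.items["D16"] == pytest.approx(1.37)

    def test_partial_year_is_annualized(self, schema):
        year = aggregate_year([make_submission(schema, quarter=1)], schema)
        assert year.items["D01"] == 4 * 72800
        assert year.items["E01"] == 52

    def test_mixed_facilities_rejected(self, schema):
        a = make_submission(schema)
        b = make_submission(schema, facility_id="H-002", quarter=2)
        with pytest.raises(ValueError):
            aggregate_year([a, b], schema)


class TestCsvRoundTrip:
    def test_write_then_read(self, schema, tmp_path):
        subs = [make_submission(schema, quarter=q) for q in (1, 2)]
        path = tmp_path / "subs.csv"
        write_submissions_csv(path, subs, schema)
        back = read_submissions_csv(path, schema)
        assert [s.items for s in back] == [s.items for s in subs]

    def test_duplicate_column_rejected(self, schema, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("facility_id,year,quarter,B01,B01\nx,2021,1,1,2\n")
        with pytest.raises(SubmissionParseError, match="duplicate column"):
            read_submissions_csv(path, schema)

    def test_comment_lines_skipped(self, schema, tmp_path):
        subs = [make_submission(schema)]
        path = tmp_path / "subs.csv"
        write_submissions_csv(path, subs, schema)
        path.write_text("# a comment\n" + path.read_text())
        assert len(read_submissions_csv(path, schema)) == 1
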