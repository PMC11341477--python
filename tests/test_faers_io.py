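"""Parsing, writing and joining of the quarterly ASCII dialect."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_signalminer.faers_io import (
    ABSENT_DATE,
    DatePrecision,
    DemoRecord,
    DrugRecord,
    ParseError,
    ReacRecord,
    SchemaError,
    TherRecord,
    join_cases,
    parse_date,
    parse_table,
    read_quarter,
    write_table,
)


@pytest.mark.parametrize(
    "raw, precision, ymd",
    [
        ("20200218", DatePrecision.DAY, (2020, 2, 18)),
        ("202002", DatePrecision.MONTH, (2020, 2, None)),
        ("2020", DatePrecision.YEAR, (2020, None, None)),
        ("20200230", DatePrecision.ABSENT, (None, None, None)),  # invalid day
        ("202013", DatePrecision.ABSENT, (None, None, None)),  # invalid month
        ("2020021", DatePrecision.ABSENT, (None, None, None)),  # 7 digits
        ("garbage", DatePrecision.ABSENT, (None, None, None)),
        ("", DatePrecision.ABSENT, (None, None, None)),
        ("NULL", DatePrecision.ABSENT, (None, None, None)),
        (None, DatePrecision.ABSENT, (None, None, None)),
    ],
)
def test_parse_date_precision_ladder(raw, precision, ymd):
    d = parse_date(raw)
    assert d.precision is precision
    assert (d.year, d.month, d.day) == ymd


@given(st.dates(min_value=__import__("datetime").date(1990, 1, 1),
                max_value=__import__("datetime").date(2035, 12, 31)))
@settings(derandomize=True, max_examples=50)
def test_day_precision_round_trips_through_text(d):
    raw = f"{d.year:04d}{d.month:02d}{d.day:02d}"
    parsed = parse_date(raw)
    assert parsed.to_date() == d
    assert parsed.to_field() == raw


def test_parse_table_maps_fields_by_header_name(tmp_path):
    # deliberately shuffled column order and mixed-case header
    path = tmp_path / "demo.txt"
    path.write_text("SEX$fda_dt$CASEID$primaryid\nF$20200301$1$101\n")
    (rec,) = parse_table(path, "DEMO")
    assert rec == DemoRecord(
        primaryid="101", caseid="1", fda_dt=parse_date("20200301"), sex="F"
    )


def test_empty_and_null_fields_become_absent(tmp_path):
    path = tmp_path / "demo.txt"
    path.write_text("primaryid$caseid$fda_dt$sex$age\n101$1$$F$NULL\n")
    (rec,) = parse_table(path, "DEMO")
    assert rec.fda_dt is ABSENT_DATE or rec.fda_dt.is_absent
    assert rec.age is None


def test_missing_required_column_is_a_schema_error(tmp_path):
    path = tmp_path / "demo.txt"
    path.write_text("primaryid$fda_dt\n101$20200301\n")
    with pytest.raises(SchemaError, match="caseid"):
        parse_table(path, "DEMO")


def test_malformed_line_error_carries_line_number(tmp_path):
    path = tmp_path / "demo.txt"
    path.write_text("primaryid$caseid\n101$1\n102\n")
    with pytest.raises(ParseError, match="line 3"):
        parse_table(path, "DEMO")


def test_unknown_role_code_rejected_with_line_number(tmp_path):
    path = tmp_path / "drug.txt"
    path.write_text("primaryid$drug_seq$role_cod$drugname\n101$1$XX$ASPIRIN\n")
    with pytest.raises(ParseError, match="line 2"):
        parse_table(path, "DRUG")


def test_latin1_fallback(tmp_path):
    path = tmp_path / "drug.txt"
    path.write_bytes(b"primaryid$drug_seq$role_cod$drugname\n101$1$PS$TEPEZZA\xae\n")
    (rec,) = parse_table(path, "DRUG")
    assert rec.drugname == "TEPEZZA\xae"


def test_quarter_round_trip_reproduces_records_exactly(tmp_path, quarter):
    """Generated tables survive write -> parse -> write -> parse unchanged."""
    directory, _ = quarter
    tables = read_quarter(directory)
    for schema, records in tables.items():
        out = tmp_path / f"{schema}.txt"
        write_table(records, out, schema)
        assert parse_table(out, schema) == records


def test_join_attaches_children_by_primaryid():
    demo = [DemoRecord("101", "1")]
    drugs = [DrugRecord("101", "1", "PS", "TEPEZZA"), DrugRecord("101", "2", "C", "ASPIRIN")]
    reacs = [ReacRecord("101", "Nausea"), ReacRecord("101", "Headache"), ReacRecord("101", "Rash")]
    result = join_cases(demo, drugs, reacs)
    (case,) = result.cases
    assert len(case.drugs) == 2 and len(case.reactions) == 3
    assert result.orphans == {"DRUG": 0, "REAC": 0, "THER": 0}


def test_join_counts_orphans_instead_of_attaching():
    result = join_cases(
        [DemoRecord("101", "1")],
        [DrugRecord("999", "1", "PS", "X")],
        [],
        [TherRecord("999", "1")],
    )
    assert result.orphans == {"DRUG": 1, "REAC": 0, "THER": 1}
    assert result.cases[0].drugs == [] and result.cases[0].therapies == []


def test_join_conserves_child_rows_on_synthetic_quarter(quarter, joined):
    """attached + orphaned = input child count, against the generator ledger."""
    _, truth = quarter
    by_pid = {c.primaryid: c for c in joined.cases}
    for pid, links in truth.link_counts.items():
        case = by_pid[pid]
        assert (len(case.drugs), len(case.reactions), len(case.therapies)) == (
            links["drug"], links["reac"], links["ther"],
        )
    assert sum(joined.orphans.values()) == 0
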