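"""Darwin Core record I/O: reading, candidate filtering, harmonized output."""

import zipfile

import pytest

from dwctraits import (
    FormatError,
    HarmonizedTraits,
    OccurrenceRecord,
    filter_candidates,
    read_occurrences,
    write_harmonized,
)
from dwctraits.records import HARMONIZED_COLUMNS


def test_reads_one_record_per_row(csv_file):
    path = csv_file(
        "occurrenceID,dynamicProperties\nr1,total length: 10 mm\nr2,wt=5g\n"
    )
    recs = read_occurrences(path)
    assert len(recs) == 2
    assert recs[0].record_id == "r1"
    assert recs[0].dynamic_properties == "total length: 10 mm"


def test_header_only_file_yields_empty_sequence(csv_file):
    assert read_occurrences(csv_file("occurrenceID,sex\n")) == []


def test_unrecognizable_header_raises_format_error(csv_file):
    with pytest.raises(FormatError):
        read_occurrences(csv_file("foo,bar\n1,2\n"))


def test_header_matching_is_case_insensitive_and_prefix_tolerant(csv_file):
    path = csv_file("dwc:OccurrenceID\tDYNAMICPROPERTIES\nr1\tsex=male\n",
                    name="records.tsv")
    recs = read_occurrences(path, dialect="tsv")
    assert recs[0].record_id == "r1"
    assert recs[0].dynamic_properties == "sex=male"


def test_unknown_columns_pass_through(csv_file):
    recs = read_occurrences(csv_file("occurrenceID,catalogNumber\nr1,CN-7\n"))
    assert recs[0].extras == {"catalogNumber": "CN-7"}


def test_dwca_core_reading(tmp_path):
    meta = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core fieldsTerminatedBy="," ignoreHeaderLines="1">
    <files><location>occurrence.csv</location></files>
    <id index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/dynamicProperties"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/sex"/>
  </core>
</archive>"""
    core = "id,props,sex\nr1,TL=44,female\n"
    archive = tmp_path / "dwca.zip"
    with zipfile.ZipFile(archive, "w") as zf:
        zf.writestr("meta.xml", meta)
        zf.writestr("occurrence.csv", core)
    recs = read_occurrences(archive, dialect="dwca-core")
    assert len(recs) == 1
    assert recs[0].record_id == "r1"
    assert recs[0].dynamic_properties == "TL=44"
    assert recs[0].sex_field == "female"


@pytest.mark.parametrize(
    "dp,remarks,notes,kept",
    [
        ("", "", "wt 5 g", True),
        ("", "", "", False),
        ("NULL", "NA", "  ", False),
        ("total length: 3 mm", "", "", True),
    ],
)
def test_filter_candidates_null_semantics(dp, remarks, notes, kept):
    rec = OccurrenceRecord(
        record_id="r1",
        dynamic_properties=dp,
        occurrence_remarks=remarks,
        field_notes=notes,
    )
    assert (filter_candidates([rec]) == [rec]) is kept


def test_filter_preserves_order_and_is_idempotent():
    recs = [
        OccurrenceRecord(record_id=f"r{i}", field_notes="x" if i % 3 else "")
        for i in range(10)
    ]
    once = filter_candidates(recs)
    assert [r.record_id for r in once] == [
        r.record_id for r in recs if r.field_notes
    ]
    assert filter_candidates(once) == once
    assert len(once) <= len(recs)


def test_write_harmonized_columns_and_serialization(tmp_path):
    rec = OccurrenceRecord(record_id="r1", dynamic_properties="x")
    traits = HarmonizedTraits(
        hasLength=True, lengthInMM=235.0, lengthType="total length",
        wereLengthUnitsInferred=True,
    )
    out = tmp_path / "out.csv"
    write_harmonized([(rec, traits)], out)
    lines = out.read_text().splitlines()
    header = lines[0].split(",")
    assert header[-len(HARMONIZED_COLUMNS):] == HARMONIZED_COLUMNS
    row = dict(zip(header, lines[1].split(",")))
    assert row["lengthInMM"] == "235"
    assert row["hasLength"] == "true"
    assert row["hasMass"] == "false"
    assert row["massInG"] == ""


def test_round_trip_identity(tmp_path):
    recs = [
        OccurrenceRecord(record_id="r1", taxon_class="Aves", genus="Turdus",
                         specific_epithet="migratorius",
                         dynamic_properties="total length: 235 mm; sex: male",
                         extras={"catalogNumber": "X1"}),
        OccurrenceRecord(record_id="r2", field_notes="235-97-31-25=71.9"),
    ]
    out = tmp_path / "h.csv"
    write_harmonized([(r, HarmonizedTraits()) for r in recs], out)
    back = read_occurrences(out)
    for orig, rb in zip(recs, back):
        for attr in ("record_id", "taxon_class", "genus", "specific_epithet",
                     "dynamic_properties", "occurrence_remarks", "field_notes"):
            assert getattr(orig, attr) == getattr(rb, attr)
        assert rb.extras.get("catalogNumber", "") == orig.extras.get(
            "catalogNumber", "")
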