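"""Extraction engine: precedence tiers, shorthand, guards, provenance."""

import pytest
from hypothesis import given, settings, strategies as st

from dwctraits import (
    OccurrenceRecord,
    extract_record,
    parse_length,
    parse_lifestage,
    parse_mass,
    parse_sex,
    parse_shorthand,
)


def quads(exts):
    return [(e.trait_type, e.value, e.units) for e in exts]


class TestParseLength:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("total length: 230 mm", [("total length", "230", "mm")]),
            ("Total Length = 230mm", [("total length", "230", "mm")]),
            ("total length: 230", [("total length", "230", "inferred")]),
            ("SVL 44", [("snout-vent length", "44", "inferred")]),
            ("ToL 120 mm", [("total length", "120", "mm")]),
            ("totalLengthInMM=235", [("total length", "235", "mm")]),
            ("fork length 88 cm", [("fork length", "88", "cm")]),
            ("", []),
            ("no measurements here", []),
            # generic-key guard: a preceding word means another measurement
            ("tail length 30 mm", []),
            # ambiguous English "in" is skipped rather than misread as inches
            ("total length: 10 in the stream", []),
        ],
    )
    def test_hand_parse_oracle(self, lexicon, text, expected):
        assert quads(parse_length(text, lexicon)) == expected

    def test_range_extraction(self, lexicon):
        (ext,) = parse_length("standard length: 20-35 mm", lexicon)
        assert ext.trait_type == "standard length"
        assert ext.value == ("20", "35")
        assert ext.units == "mm"
        assert ext.is_range

    def test_at_most_one_extraction_per_subtype(self, lexicon):
        exts = parse_length("total length: 100 mm; total length: 200 mm", lexicon)
        assert quads(exts) == [("total length", "100", "mm")]

    def test_explicit_key_outranks_overlapping_generic_key(self, lexicon):
        # "length" alone is a total-length synonym but must not fire inside
        # "standard length"
        exts = parse_length("standard length: 20 mm", lexicon)
        assert quads(exts) == [("standard length", "20", "mm")]

    def test_two_subtypes_coexist(self, lexicon):
        exts = parse_length("total length: 200 mm; SVL 90", lexicon)
        assert set(quads(exts)) == {
            ("total length", "200", "mm"),
            ("snout-vent length", "90", "inferred"),
        }


class TestParseMass:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("weight=71.9 g", [("body mass", "71.9", "g")]),
            ("body mass: 20 kg", [("body mass", "20", "kg")]),
            ("mass not recorded", []),
            ("wt: 12 gms", [("body mass", "12", "gms")]),
            ("weight: 2.5 lbs", [("body mass", "2.5", "lbs")]),
            ("weight: 2 lbs 3 oz", [("body mass", ("2", "3"), "lb+oz")]),
            ("weighs about 200", []),  # key-less numeric never taken as mass
            ("", []),
        ],
    )
    def test_hand_parse_oracle(self, lexicon, text, expected):
        assert quads(parse_mass(text, lexicon)) == expected

    def test_decimal_comma_accepted(self, lexicon):
        (ext,) = parse_mass("weight: 71,9 g", lexicon)
        assert ext.value == "71,9"  # verbatim; normalized downstream


class TestParseShorthand:
    def test_printed_mammalogy_example(self):
        exts = parse_shorthand("235-97-31-25 = 71.9")
        assert quads(exts) == [
            ("total length", "235", "inferred"),
            ("body mass", "71.9", "inferred"),
        ]

    @pytest.mark.parametrize("text", ["12-05-2003", "2-3-1999", "", "only words"])
    def test_rejects_dates_and_non_matches(self, text):
        assert parse_shorthand(text) == []

    def test_three_part_chain_without_mass(self):
        exts = parse_shorthand("110-55-20")
        assert quads(exts) == [("total length", "110", "inferred")]

    def test_middle_values_not_emitted(self):
        values = [e.value for e in parse_shorthand("235-97-31-25 = 71.9")]
        assert "97" not in values and "31" not in values and "25" not in values


class TestParseSex:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("sex=male;", [("sex", "male", "")]),
            ("sex: F", [("sex", "F", "")]),
            ("an adult female", [("sex", "female", "")]),
            ("males and females in lot", []),
            ("male and female in lot", []),  # conflicting tokens suppressed
            ("sex=male; another male seen", [("sex", "male", "")]),
            ("F 23", []),  # bare single letters need a key
            ("", []),
        ],
    )
    def test_hand_parse_oracle(self, text, expected):
        assert quads(parse_sex(text)) == expected


class TestParseLifestage:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("age class: adult", [("life stage", "adult", "")]),
            ("lifestage=juvenile", [("life stage", "juvenile", "")]),
            ("age: subadult", [("life stage", "subadult", "")]),
            ("adult", []),  # bare stage words need a key in default mode
            ("", []),
        ],
    )
    def test_hand_parse_oracle(self, text, expected):
        assert quads(parse_lifestage(text)) == expected

    def test_aggressive_mode_extracts_and_flags_bare_tokens(self):
        (ext,) = parse_lifestage("adult", aggressive=True)
        assert ext.value == "adult"
        assert ext.keyless


class TestExtractRecord:
    def test_field_priority(self, lexicon):
        rec = OccurrenceRecord(
            record_id="r1",
            dynamic_properties="total length: 100 mm",
            field_notes="total length: 200 mm",
        )
        (ext,) = extract_record(rec, lexicon)
        assert ext.value == "100"
        assert ext.source_field == "dynamicProperties"

    def test_traits_gathered_across_fields(self, lexicon):
        rec = OccurrenceRecord(
            record_id="r1",
            occurrence_remarks="sex: male",
            field_notes="235-97-31-25 = 71.9",
        )
        exts = {e.trait_type: e for e in extract_record(rec, lexicon)}
        assert exts["sex"].source_field == "occurrenceRemarks"
        assert exts["total length"].source_field == "fieldNotes"
        assert exts["body mass"].value == "71.9"

    def test_empty_record_empty_result(self, lexicon):
        assert extract_record(OccurrenceRecord(record_id="r1"), lexicon) == []


class TestInvariants:
    @given(st.text(max_size=120))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_determinism_and_verbatim_provenance(self, text):
        exts = (
            parse_shorthand(text) + parse_sex(text) + parse_lifestage(text)
        )
        again = (
            parse_shorthand(text) + parse_sex(text) + parse_lifestage(text)
        )
        assert [(e.trait_type, e.value) for e in exts] == [
            (e.trait_type, e.value) for e in again
        ]
        for e in exts:
            start, end = e.span
            assert 0 <= start <= end <= len(text)
            assert text[start:end] == e.verbatim_match

    @given(st.text(max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_prefix_stability_for_explicit_keys(self, lexicon, suffix):
        base = "total length: 230 mm"
        exts = parse_length(base + "; " + suffix, lexicon)
        totals = [e for e in exts if e.trait_type == "total length"]
        assert totals and totals[0].value == "230"
        assert totals[0].units == "mm"

    def test_length_verbatim_spans(self, lexicon):
        text = "specimen; total length: 230 mm, weight: 12 g"
        for e in parse_length(text, lexicon) + parse_mass(text, lexicon):
            start, end = e.span
            assert text[start:end] == e.verbatim_match
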