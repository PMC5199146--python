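"""Darwin Core occurrence record I/O.

Reads occurrence records from CSV/TSV exports or from the occurrence core of
a Darwin Core Archive, filters them down to candidates that carry free text
in any of the three generic fields (``dynamicProperties``,
``occurrenceRemarks``, ``fieldNotes``), and writes records back out with the
harmonized trait columns appended.

Header matching is case-insensitive on Darwin Core simple names, with or
without the ``dwc:`` namespace prefix, because publishers vary in how they
label exports.
"""

from __future__ import annotations

import csv
import io
import logging
import xml.etree.ElementTree as ET
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

#: Darwin Core simple names recognized in headers, mapped to attribute names.
DWC_FIELD_MAP = {
    "occurrenceid": "record_id",
    "class": "taxon_class",
    "genus": "genus",
    "specificepithet": "specific_epithet",
    "scientificname": "scientific_name",
    "sex": "sex_field",
    "lifestage": "life_stage_field",
    "dynamicproperties": "dynamic_properties",
    "occurrenceremarks": "occurrence_remarks",
    "fieldnotes": "field_notes",
}

#: Canonical output spelling for each attribute (inverse of DWC_FIELD_MAP).
DWC_CANONICAL_HEADER = {
    "record_id": "occurrenceID",
    "taxon_class": "class",
    "genus": "genus",
    "specific_epithet": "specificEpithet",
    "scientific_name": "scientificName",
    "sex_field": "sex",
    "life_stage_field": "lifeStage",
    "dynamic_properties": "dynamicProperties",
    "occurrence_remarks": "occurrenceRemarks",
    "field_notes": "fieldNotes",
}

#: Harmonized columns appended by :func:`write_harmonized`, in contract order.
HARMONIZED_COLUMNS = [
    "hasLength",
    "hasMass",
    "hasSex",
    "hasLifeStage",
    "lengthInMM",
    "massInG",
    "wereLengthUnitsInferred",
    "wereMassUnitsInferred",
    "derivedSex",
    "derivedLifeStage",
    "lengthType",
]

#: Tokens that count as empty content, approximating SQL NULL in CSV exports.
EMPTY_TOKENS = {"", "null", "na"}


class FormatError(ValueError):
    """Input file header does not expose any recognizable Darwin Core term."""


@dataclass
class OccurrenceRecord:
    """One specimen or observation row with its Darwin Core fields.

    Text fields hold verbatim input (surrounding whitespace aside); unknown
    input columns are retained in ``extras`` so output can reproduce input.
    """

    record_id: str
    taxon_class: str = ""
    genus: str = ""
    specific_epithet: str = ""
    scientific_name: str = ""
    sex_field: str = ""
    life_stage_field: str = ""
    dynamic_properties: str = ""
    occurrence_remarks: str = ""
    field_notes: str = ""
    collection_context: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def free_text_fields(self) -> list[tuple[str, str]]:
        """The three generic free-text fields, in extraction priority order."""
        return [
            ("dynamicProperties", self.dynamic_properties),
            ("occurrenceRemarks", self.occurrence_remarks),
            ("fieldNotes", self.field_notes),
        ]


def _normalize_header(name: str) -> str:
    name = name.strip().lower()
    if ":" in name:  # strip namespace prefix such as "dwc:"
        name = name.rsplit(":", 1)[1]
    return name


def _records_from_rows(
    header: Sequence[str], rows: Iterable[Sequence[str]]
) -> list[OccurrenceRecord]:
    mapping: list[tuple[int, str | None, str]] = []
    recognized = 0
    for i, col in enumerate(header):
        attr = DWC_FIELD_MAP.get(_normalize_header(col))
        if attr is not None:
            recognized += 1
        mapping.append((i, attr, col))
    if recognized == 0:
        raise FormatError(
            "no recognizable Darwin Core terms in header; expected at least "
            "one of: " + ", ".join(sorted(DWC_CANONICAL_HEADER.values()))
        )

    records = []
    for rownum, row in enumerate(rows):
        rec = OccurrenceRecord(record_id="")
        for i, attr, colname in mapping:
            value = row[i].strip() if i < len(row) else ""
            if attr is None:
                rec.extras[colname] = value
            else:
                setattr(rec, attr, value)
        if not rec.record_id:
            rec.record_id = f"row-{rownum + 1}"
        records.append(rec)
    return records


def _read_delimited(text: str, delimiter: str) -> list[OccurrenceRecord]:
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("file is empty; no header row found") from None
    return _records_from_rows(header, reader)


def _read_dwca_core(path: Path) -> list[OccurrenceRecord]:
    """Minimal Darwin Core Archive reader: occurrence core only.

    Parses ``meta.xml`` for the core file name, field indices, and delimiter.
    Extensions are ignored with a logged warning.
    """
    ns = "{http://rs.tdwg.org/dwc/text/}"
    with zipfile.ZipFile(path) as zf:
        with zf.open("meta.xml") as fh:
            meta = ET.parse(fh).getroot()
        core = meta.find(f"{ns}core")
        if core is None:
            core = meta.find("core")  # tolerate missing namespace
        if core is None:
            raise FormatError("meta.xml has no <core> element")
        if meta.findall(f"{ns}extension") or meta.findall("extension"):
            log.warning("Darwin Core Archive extensions present; ignored")

        delim = core.get("fieldsTerminatedBy", ",")
        delim = delim.encode().decode("unicode_escape")
        skip = int(core.get("ignoreHeaderLines", "0"))
        loc = core.find(f"{ns}files/{ns}location")
        if loc is None:
            loc = core.find("files/location")
        if loc is None or not loc.text:
            raise FormatError("meta.xml core has no file location")

        # Column index -> term simple name, from <id> and <field> elements.
        colnames: dict[int, str] = {}
        id_el = core.find(f"{ns}id")
        if id_el is None:
            id_el = core.find("id")
        if id_el is not None:
            colnames[int(id_el.get("index", "0"))] = "occurrenceID"
        for f_el in list(core.findall(f"{ns}field")) + list(core.findall("field")):
            idx = f_el.get("index")
            term = f_el.get("term", "")
            if idx is not None:
                colnames[int(idx)] = term.rstrip("/").rsplit("/", 1)[-1]

        width = max(colnames) + 1 if colnames else 0
        header = [colnames.get(i, f"column{i}") for i in range(width)]

        raw = zf.read(loc.text).decode("utf-8", errors="replace")
        rows = list(csv.reader(io.StringIO(raw), delimiter=delim))[skip:]
    return _records_from_rows(header, rows)


def read_occurrences(
    path: str | Path, dialect: str = "csv"
) -> list[OccurrenceRecord]:
    """Read occurrence records from a file.

    Parameters
    ----------
    path
        Input file. For ``dwca-core`` this is a Darwin Core Archive zip
        containing ``meta.xml`` and the occurrence core text file.
    dialect
        One of ``csv``, ``tsv``, ``dwca-core``.

    Raises
    ------
    FormatError
        If the header exposes no recognizable Darwin Core term.
    """
    path = Path(path)
    if dialect == "dwca-core":
        return _read_dwca_core(path)
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    raw = path.read_bytes()
    text = raw.decode("utf-8", errors="replace")
    if "�" in text:
        log.warning("%s: invalid UTF-8 bytes replaced", path)
    return _read_delimited(text, "\t" if dialect == "tsv" else ",")


def _is_empty(value: str) -> bool:
    return value.strip().lower() in EMPTY_TOKENS


def filter_candidates(
    records: Iterable[OccurrenceRecord],
) -> list[OccurrenceRecord]:
    """Keep records with content in any of the three generic free-text fields.

    ``"NULL"``, ``"NA"`` and whitespace-only values count as empty,
    approximating the SQL ``IS NOT NULL`` filter on CSV exports. Input order
    is preserved; the operation is idempotent.
    """
    return [
        r
        for r in records
        if not (
            _is_empty(r.dynamic_properties)
            and _is_empty(r.occurrence_remarks)
            and _is_empty(r.field_notes)
        )
    ]


def _serialize_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        # minimal decimal representation: 235.0 -> "235", 71.9 -> "71.9"
        if value == int(value):
            return str(int(value))
        return repr(value)
    return str(value)


def write_occurrences(
    records: Sequence[OccurrenceRecord], path: str | Path
) -> None:
    """Write records as a Darwin Core CSV (canonical headers + passthrough)."""
    extra_cols: list[str] = []
    for rec in records:
        for col in rec.extras:
            if col not in extra_cols:
                extra_cols.append(col)
    header = list(DWC_CANONICAL_HEADER.values()) + extra_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [getattr(rec, attr) for attr in DWC_CANONICAL_HEADER]
            row += [rec.extras.get(col, "") for col in extra_cols]
            writer.writerow(row)


def write_harmonized(
    pairs: Sequence[tuple[OccurrenceRecord, "HarmonizedTraits"]],
    path: str | Path,
) -> None:
    """Write records with the eleven harmonized trait columns appended.

    Column order and spelling are part of the public contract: the original
    Darwin Core columns first, then any passthrough columns, then
    ``hasLength`` ... ``lengthType``. Booleans serialize as ``true``/``false``
    and absent numerics as the empty string.
    """
    extra_cols: list[str] = []
    for rec, _ in pairs:
        for col in rec.extras:
            # harmonized columns re-read from our own output are regenerated,
            # not passed through, so re-serialization is stable
            if col not in extra_cols and col not in HARMONIZED_COLUMNS:
                extra_cols.append(col)
    header = list(DWC_CANONICAL_HEADER.values()) + extra_cols + HARMONIZED_COLUMNS

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec, traits in pairs:
            row = [getattr(rec, attr) for attr in DWC_CANONICAL_HEADER]
            row += [rec.extras.get(col, "") for col in extra_cols]
            row += [_serialize_cell(traits.as_row()[col]) for col in HARMONIZED_COLUMNS]
            writer.writerow(row)
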