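"""Rule-based trait extraction from occurrence free text.

The extraction engine runs ordered regular-expression tiers over the three
generic Darwin Core free-text fields and emits one
:class:`RawExtraction` quadruplet per trait found: the source field, the
standardized trait type, the verbatim value, and the units (or ``inferred``
when none were written).

Precedence within a field, per trait type:

1. explicit key with units              ``total length: 230 mm``
2. explicit key without units           ``total length: 230``
3. abbreviation with delimiter          ``TL=230`` / ``SVL 44``
4. mammalogy shorthand                  ``235-97-31-25 = 71.9``

Earlier tiers claim their character spans; later-tier matches overlapping a
claimed span are masked. Matching is case-insensitive and anchored on word
boundaries throughout; patterns favor missing a value over inventing one,
so unparseable content yields no extraction rather than an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import (
    LENGTH_SUBTYPES,
    LexiconEntry,
    load_lexicon,
    normalize_synonym,
)
from .records import OccurrenceRecord

TRAIT_BODY_MASS = "body mass"
TRAIT_SEX = "sex"
TRAIT_LIFE_STAGE = "life stage"

#: Numeric token: integer or decimal with point or comma.
NUM = r"\d+(?:[.,]\d+)?"
#: Range token: two numerics joined by a dash, not part of a longer chain.
RANGE = rf"({NUM})\s*[-–—]\s*({NUM})(?!\s*[-–—]\s*\d)"

LENGTH_UNITS = r"(?:millimeters?|millimetres?|centimeters?|centimetres?|meters?|metres?|mm|cm|m|inches|inch|in|feet|foot|ft)"
MASS_UNITS = r"(?:grams?|gms?|g|kilograms?|kgs?|kg|pounds?|lbs?|lb|ounces?|ozs?|oz)"

_KEY_DELIM = r"\s*(?:[:=]\s*|\s)"  # key/value separator: colon, equals, space
_ABBR_DELIM = r"[\s:=.]{0,3}"  # abbreviation needs a numeric within 3 chars


@dataclass
class RawExtraction:
    """One extracted trait quadruplet plus provenance.

    ``value`` is the verbatim numeric string (or a pair of strings for
    ranges and compound lb+oz masses, or a categorical token for sex/life
    stage); conversion to numbers happens downstream so that provenance is
    preserved exactly.
    """

    trait_type: str
    value: str | tuple[str, str]
    units: str  # unit token, "inferred", or "" for categorical traits
    verbatim_match: str
    span: tuple[int, int]
    source_field: str = ""
    is_range: bool = False
    keyless: bool = False


def _synonym_pattern(synonym: str) -> str:
    """Separator-tolerant pattern for one lexicon synonym."""
    parts = normalize_synonym(synonym)
    # allow optional separators between every pair of characters that sit on
    # a word-piece boundary; simplest robust form: split camel/space form
    words = re.sub(r"(?<=[a-z])(?=[A-Z])", " ", synonym)
    words = re.split(r"[\s_.\-]+", words.strip())
    joined = r"[\s_.\-]*".join(re.escape(w) for w in words if w)
    return joined if joined else re.escape(parts)


def _entries(
    lexicon: Sequence[LexiconEntry], trait_class: str, kind: str
) -> list[LexiconEntry]:
    return [e for e in lexicon if e.trait_class == trait_class and e.match_kind == kind]


def _key_alternation(entries: Iterable[LexiconEntry]) -> dict[str, str]:
    """canonical -> alternation pattern over all its synonyms (longest first)."""
    out: dict[str, list[str]] = {}
    for e in entries:
        out.setdefault(e.canonical, []).extend(e.synonyms)
    return {
        canon: "|".join(
            _synonym_pattern(s) for s in sorted(syns, key=len, reverse=True)
        )
        for canon, syns in out.items()
    }


def _overlaps(span: tuple[int, int], claimed: list[tuple[int, int]]) -> bool:
    return any(span[0] < e and s < span[1] for s, e in claimed)


def _value_groups(m: re.Match) -> tuple[str | tuple[str, str], bool]:
    """Pull (value, is_range) out of a match with 'lo','hi','val' groups."""
    if m.groupdict().get("lo"):
        return (m["lo"], m["hi"]), True
    return m["val"], False


#: One-word keys that are common nouns; as a false-positive guard they are
#: rejected when directly preceded by another word ("tail length 30").
GENERIC_KEYS = {"length", "mass", "weight"}


def _tiered_keyed_patterns(
    key_pat: str, units_pat: str
) -> list[tuple[int, re.Pattern]]:
    """Tier-1 (with units) and tier-2 (without) patterns for one key set."""
    value = rf"(?:(?P<lo>{NUM})\s*[-–—]\s*(?P<hi>{NUM})(?!\s*[-–—]\s*\d)|(?P<val>{NUM}))"
    with_units = re.compile(
        rf"\b(?P<key>{key_pat})\b{_KEY_DELIM}{value}\s*(?P<units>{units_pat})\b",
        re.IGNORECASE,
    )
    without_units = re.compile(
        rf"\b(?P<key>{key_pat})\b{_KEY_DELIM}{value}(?!\s*{units_pat}\b)(?![.,]?\d)",
        re.IGNORECASE,
    )
    return [(1, with_units), (2, without_units)]


def _abbrev_patterns(abbr_pat: str, units_pat: str) -> list[tuple[int, re.Pattern]]:
    value = rf"(?:(?P<lo>{NUM})\s*[-–—]\s*(?P<hi>{NUM})(?!\s*[-–—]\s*\d)|(?P<val>{NUM}))"
    pat = re.compile(
        rf"\b(?P<key>{abbr_pat})\b{_ABBR_DELIM}{value}\s*(?P<units>{units_pat})?\b",
        re.IGNORECASE,
    )
    return [(3, pat)]


#: Unit suffixes embedded in keys themselves ("totalLengthInMM").
_KEY_UNIT_SUFFIXES = [
    ("inmillimeters", "mm"), ("inmm", "mm"), ("incm", "cm"),
    ("ingrams", "g"), ("ing", "g"), ("inkg", "kg"), ("inlbs", "lb"),
]


def _units_from_key(key: str | None, units: str) -> str:
    """Keys that name their units override an 'inferred' default."""
    if units != "inferred" or not key:
        return units
    key_norm = normalize_synonym(key)
    for suffix, unit in _KEY_UNIT_SUFFIXES:
        if key_norm.endswith(suffix):
            return unit
    return units


def _rejected_match(text: str, m: re.Match, units: str) -> bool:
    """False-positive guards applied to every keyed candidate."""
    key = m.groupdict().get("key")
    if key and normalize_synonym(key) in GENERIC_KEYS:
        if re.search(r"[A-Za-z][\s_.\-]*$", text[: m.start()]):
            return True  # "tail length 30", "gonad weight 5 g"
    if units == "in" and re.match(r"\s+[A-Za-z]", text[m.end():]):
        return True  # English preposition, not inches: skip as ambiguous
    return False


def _collect_keyed_matches(
    text: str,
    canon_patterns: dict[str, list[tuple[int, re.Pattern]]],
) -> list[tuple[int, int, int, str, re.Match]]:
    """All candidate (tier, start, -keylen, canonical, match) tuples."""
    found = []
    for canon, tiered in canon_patterns.items():
        for tier, pat in tiered:
            for m in pat.finditer(text):
                found.append((tier, m.start(), -(len(m.group(0))), canon, m))
    return found


def _resolve(
    text: str,
    canon_patterns: dict[str, list[tuple[int, re.Pattern]]],
    units_default: str,
    claimed: list[tuple[int, int]],
) -> list[RawExtraction]:
    """Apply tier precedence and span masking; one extraction per canonical."""
    taken: dict[str, RawExtraction] = {}
    candidates = sorted(
        _collect_keyed_matches(text, canon_patterns), key=lambda t: t[:3]
    )
    for tier, _start, _nlen, canon, m in candidates:
        span = (m.start(), m.end())
        if canon in taken or _overlaps(span, claimed):
            continue
        value, is_range = _value_groups(m)
        units = (m.groupdict().get("units") or "").lower() or units_default
        units = _units_from_key(m.groupdict().get("key"), units)
        if _rejected_match(text, m, units):
            continue
        taken[canon] = RawExtraction(
            trait_type=canon,
            value=value,
            units=units,
            verbatim_match=m.group(0),
            span=span,
            is_range=is_range,
        )
        claimed.append(span)
    return list(taken.values())


def _length_patterns(
    lexicon: Sequence[LexiconEntry],
) -> dict[str, list[tuple[int, re.Pattern]]]:
    explicit = _key_alternation(_entries(lexicon, "body_length", "explicit_key"))
    abbrev = _key_alternation(_entries(lexicon, "body_length", "abbreviation"))
    patterns: dict[str, list[tuple[int, re.Pattern]]] = {}
    for canon in LENGTH_SUBTYPES:
        tiers: list[tuple[int, re.Pattern]] = []
        if canon in explicit:
            tiers += _tiered_keyed_patterns(explicit[canon], LENGTH_UNITS)
        if canon in abbrev:
            tiers += _abbrev_patterns(abbrev[canon], LENGTH_UNITS)
        if tiers:
            patterns[canon] = tiers
    return patterns


def parse_length(
    text: str, lexicon: Sequence[LexiconEntry] | None = None
) -> list[RawExtraction]:
    """Extract body-length measurements (five subtypes) from one field.

    At most one extraction per subtype. Shorthand-derived total length is
    the last tier and is masked by any earlier overlapping match.
    """
    if not text:
        return []
    lexicon = lexicon if lexicon is not None else load_lexicon()
    claimed: list[tuple[int, int]] = []
    out = _resolve(text, _length_patterns(lexicon), "inferred", claimed)
    if not any(x.trait_type == "total length" for x in out):
        for sh in parse_shorthand(text):
            if sh.trait_type == "total length" and not _overlaps(sh.span, claimed):
                out.append(sh)
                break
    return out


def _mass_patterns(
    lexicon: Sequence[LexiconEntry],
) -> dict[str, list[tuple[int, re.Pattern]]]:
    explicit = _key_alternation(_entries(lexicon, "body_mass", "explicit_key"))
    abbrev = _key_alternation(_entries(lexicon, "body_mass", "abbreviation"))
    tiers: list[tuple[int, re.Pattern]] = []
    key_pat = explicit.get(TRAIT_BODY_MASS, "")
    if key_pat:
        # compound Imperial form first: "weight: 2 lbs 3 oz"
        compound = re.compile(
            rf"\b(?:{key_pat})\b{_KEY_DELIM}(?P<lbs>{NUM})\s*(?:pounds?|lbs?)\.?,?\s*"
            rf"(?P<oz>{NUM})\s*(?:ounces?|ozs?)\b",
            re.IGNORECASE,
        )
        tiers.append((0, compound))
        tiers += _tiered_keyed_patterns(key_pat, MASS_UNITS)
    if TRAIT_BODY_MASS in abbrev:
        tiers += _abbrev_patterns(abbrev[TRAIT_BODY_MASS], MASS_UNITS)
    return {TRAIT_BODY_MASS: tiers}


def parse_mass(
    text: str, lexicon: Sequence[LexiconEntry] | None = None
) -> list[RawExtraction]:
    """Extract a body-mass measurement from one field.

    Key-less numerics are never taken as mass except through the mammalogy
    shorthand; compound Imperial values ("2 lbs 3 oz") are recognized.
    """
    if not text:
        return []
    lexicon = lexicon if lexicon is not None else load_lexicon()
    claimed: list[tuple[int, int]] = []
    taken: dict[str, RawExtraction] = {}
    candidates = sorted(
        _collect_keyed_matches(text, _mass_patterns(lexicon)), key=lambda t: t[:3]
    )
    for tier, _s, _nl, canon, m in candidates:
        span = (m.start(), m.end())
        if canon in taken or _overlaps(span, claimed):
            continue
        gd = m.groupdict()
        if "lbs" in gd and gd.get("lbs") is not None:
            value: str | tuple[str, str] = (gd["lbs"], gd["oz"])
            units, is_range = "lb+oz", False
        else:
            value, is_range = _value_groups(m)
            if is_range:
                continue  # mass ranges are not produced
            units = _units_from_key(gd.get("key"), (gd.get("units") or "").lower() or "inferred")
        if _rejected_match(text, m, units):
            continue
        taken[canon] = RawExtraction(
            trait_type=canon,
            value=value,
            units=units,
            verbatim_match=m.group(0),
            span=span,
        )
        claimed.append(span)
    out = list(taken.values())
    if not out:
        for sh in parse_shorthand(text):
            if sh.trait_type == TRAIT_BODY_MASS:
                out.append(sh)
                break
    return out


#: 3-5 dash-separated numerics, optional "= mass" suffix.
_SHORTHAND = re.compile(
    rf"(?<![\d.,/\-])(?P<chain>{NUM}(?:\s*-\s*{NUM}){{2,4}})"
    rf"(?:\s*=\s*(?P<mass>{NUM}))?(?!\s*-\s*\d)(?![.,]?\d)"
)


def _date_like(parts: list[str]) -> bool:
    """Guard: a 3-part integer chain that reads as a calendar date."""
    if len(parts) != 3 or any("." in p or "," in p for p in parts):
        return False
    if any(len(p) == 4 and 1200 <= int(p) <= 2199 for p in parts):
        return True
    # leading zeros ("12-05-03") are a date-writing convention
    return any(len(p) > 1 and p[0] == "0" for p in parts)


def parse_shorthand(text: str) -> list[RawExtraction]:
    """Parse the mammalogy measurement shorthand.

    The convention ``total-tail-hindfoot-ear = mass`` writes 3-5
    dash-separated lengths, customarily in millimeters, optionally followed
    by ``=`` and a mass in grams. Only the first numeric (total length) and
    the post-``=`` numeric (body mass) are emitted, both with inferred
    units; the middle values are matched but discarded. Date-like chains
    (``12-05-2003``) are rejected.
    """
    out: list[RawExtraction] = []
    for m in _SHORTHAND.finditer(text or ""):
        parts = re.split(r"\s*-\s*", m["chain"])
        if _date_like(parts):
            continue
        span = (m.start(), m.end())
        out.append(
            RawExtraction(
                trait_type="total length",
                value=parts[0],
                units="inferred",
                verbatim_match=m.group(0),
                span=span,
            )
        )
        if m["mass"] is not None:
            out.append(
                RawExtraction(
                    trait_type=TRAIT_BODY_MASS,
                    value=m["mass"],
                    units="inferred",
                    verbatim_match=m.group(0),
                    span=span,
                )
            )
    return out


_SEX_KEYED = re.compile(
    r"\bsex\b\s*[:=]?\s*(?P<val>males?|females?|[mf])\b", re.IGNORECASE
)
_SEX_BARE = re.compile(r"\b(?P<val>male|female)\b", re.IGNORECASE)


def _sex_norm(token: str) -> str:
    t = token.lower().rstrip("s")
    return {"m": "male", "f": "female"}.get(t, t)


def parse_sex(text: str) -> list[RawExtraction]:
    """Extract sex when keyed (``sex=F``) or as an isolated bare token.

    Single-letter ``m``/``f`` are only accepted when keyed. When a field
    mentions conflicting sexes (verbose multi-individual remarks such as
    "male and female in lot"), nothing is emitted for that field.
    """
    if not text:
        return []
    matches: list[tuple[tuple[int, int], str, str]] = []
    for m in _SEX_KEYED.finditer(text):
        matches.append(((m.start(), m.end()), m.group(0), m["val"]))
    keyed_spans = [s for s, _, _ in matches]
    for m in _SEX_BARE.finditer(text):
        if not _overlaps((m.start(), m.end()), keyed_spans):
            matches.append(((m.start(), m.end()), m.group(0), m["val"]))
    if not matches:
        return []
    if len({_sex_norm(v) for _, _, v in matches}) > 1:
        return []  # conflicting sexes: multi-individual remark
    span, verbatim, value = min(matches, key=lambda t: t[0])
    return [
        RawExtraction(
            trait_type=TRAIT_SEX,
            value=value,
            units="",
            verbatim_match=verbatim,
            span=span,
        )
    ]


_STAGE_KEYS = r"(?:life\s*[-_]?\s*stage|age\s*[-_]?\s*class|age|stage)"
_STAGE_KEYED = re.compile(
    rf"\b{_STAGE_KEYS}\b\s*[:=]\s*(?P<val>[A-Za-z][A-Za-z \-]*?)(?=$|[;,.|()\[\]]|\s{{2,}})",
    re.IGNORECASE,
)
_STAGE_VOCAB = (
    "adult|juvenile|subadult|sub-adult|immature|nestling|fledgling|hatchling|"
    "neonate|yearling|larva|larval|tadpole|embryo|fetus|chick|pup|fawn|calf"
)
_STAGE_BARE = re.compile(rf"\b(?P<val>{_STAGE_VOCAB})\b", re.IGNORECASE)


def parse_lifestage(text: str, aggressive: bool = False) -> list[RawExtraction]:
    """Extract life stage from keyed forms (``age class: adult``).

    Bare stage words without a key ("adult" alone) are not extracted in
    default mode; with ``aggressive=True`` they are extracted and flagged
    ``keyless`` so downstream users can treat them with suspicion.
    """
    if not text:
        return []
    m = _STAGE_KEYED.search(text)
    if m:
        value = m["val"].strip()
        words = value.split()
        # keyed values are kept verbatim, but a recognized stage word is not
        # allowed to drag trailing prose with it ("age: adult specimens ...")
        if len(words) > 1 and words[0].lower() in _STAGE_VOCAB.split("|"):
            if words[1].lower() not in ("of", "year", "years"):
                value = words[0]
        return [
            RawExtraction(
                trait_type=TRAIT_LIFE_STAGE,
                value=value,
                units="",
                verbatim_match=m.group(0),
                span=(m.start(), m.end()),
            )
        ]
    if aggressive:
        b = _STAGE_BARE.search(text)
        if b:
            return [
                RawExtraction(
                    trait_type=TRAIT_LIFE_STAGE,
                    value=b["val"],
                    units="",
                    verbatim_match=b.group(0),
                    span=(b.start(), b.end()),
                    keyless=True,
                )
            ]
    return []


def extract_record(
    record: OccurrenceRecord,
    lexicon: Sequence[LexiconEntry] | None = None,
    aggressive_lifestage: bool = False,
) -> list[RawExtraction]:
    """Run all parsers over a record's three free-text fields.

    Fields are visited in priority order dynamicProperties,
    occurrenceRemarks, fieldNotes; per trait type the first field that
    yields a match wins, and every retained extraction carries its source
    field.
    """
    lexicon = lexicon if lexicon is not None else load_lexicon()
    taken: dict[str, RawExtraction] = {}
    order: list[str] = []
    for field_name, text in record.free_text_fields():
        if not text:
            continue
        found = (
            parse_length(text, lexicon)
            + parse_mass(text, lexicon)
            + parse_sex(text)
            + parse_lifestage(text, aggressive=aggressive_lifestage)
        )
        for ext in found:
            if ext.trait_type not in taken:
                ext.source_field = field_name
                taken[ext.trait_type] = ext
                order.append(ext.trait_type)
    return [taken[t] for t in order]
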