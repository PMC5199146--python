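"""Unit standardization and assembly of the harmonized output fields.

All body lengths are converted to millimeters and all body masses to grams,
the customary units for vertebrate specimens. Values whose units were never
written are assumed to be mm/g and flagged as inferred. Converted values
are truncated (not rounded) to two decimal places; inputs reported at lower
precision keep their reported precision.

Conversion uses :class:`decimal.Decimal` so that truncation operates on the
decimal representation, not on binary floating point (``71.9`` must stay
``71.9``, never become ``71.89``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation, ROUND_DOWN
from typing import Sequence

from .lexicon import LENGTH_SUBTYPES
from .parsers import (
    RawExtraction,
    TRAIT_BODY_MASS,
    TRAIT_LIFE_STAGE,
    TRAIT_SEX,
)
from .records import OccurrenceRecord

log = logging.getLogger(__name__)


class ConversionError(ValueError):
    """Value or unit token cannot be converted; the extraction is dropped."""


#: Exact conversion factors to millimeters.
LENGTH_FACTORS = {
    "mm": "1", "millimeter": "1", "millimeters": "1",
    "millimetre": "1", "millimetres": "1",
    "cm": "10", "centimeter": "10", "centimeters": "10",
    "centimetre": "10", "centimetres": "10",
    "m": "1000", "meter": "1000", "meters": "1000",
    "metre": "1000", "metres": "1000",
    "in": "25.4", "inch": "25.4", "inches": "25.4",
    "ft": "304.8", "foot": "304.8", "feet": "304.8",
    "inferred": "1",
}

#: Exact conversion factors to grams.
MASS_FACTORS = {
    "g": "1", "gm": "1", "gms": "1", "gram": "1", "grams": "1",
    "kg": "1000", "kgs": "1000", "kilogram": "1000", "kilograms": "1000",
    "lb": "453.59237", "lbs": "453.59237",
    "pound": "453.59237", "pounds": "453.59237",
    "oz": "28.349523125", "ozs": "28.349523125",
    "ounce": "28.349523125", "ounces": "28.349523125",
    "inferred": "1",
}


def _to_decimal(value) -> Decimal:
    if isinstance(value, str):
        value = value.replace(",", ".")
    try:
        d = Decimal(str(value))
    except InvalidOperation as exc:
        raise ConversionError(f"not a number: {value!r}") from exc
    if not d.is_finite():
        raise ConversionError(f"not finite: {value!r}")
    return d


def _truncate2(d: Decimal) -> float:
    """Truncate to two decimals; lower-precision inputs are unaffected."""
    if d == d.to_integral_value():
        return float(d)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def _convert(value, units: str, factors: dict[str, str], kind: str):
    d = _to_decimal(value)
    if d <= 0:
        raise ConversionError(f"non-positive {kind}: {value!r}")
    units_token = (units or "").strip().lower()
    factor = factors.get(units_token)
    if factor is None:
        raise ConversionError(f"unknown {kind} unit: {units!r}")
    return _truncate2(d * Decimal(factor)), units_token == "inferred"


def convert_length(value, units: str) -> tuple[float, bool]:
    """Convert a length to millimeters.

    Returns ``(mm, inferred)`` where ``inferred`` is true iff no units were
    written (mm assumed). Raises :class:`ConversionError` for non-positive
    values or unknown unit tokens.
    """
    return _convert(value, units, LENGTH_FACTORS, "length")


def convert_mass(value, units: str) -> tuple[float, bool]:
    """Convert a mass to grams.

    ``units="lb+oz"`` takes ``value`` as a ``(pounds, ounces)`` pair and
    sums the components. Returns ``(g, inferred)``.
    """
    if units == "lb+oz":
        if not (isinstance(value, (tuple, list)) and len(value) == 2):
            raise ConversionError("lb+oz units require a (lb, oz) value pair")
        lbs = _to_decimal(value[0])
        oz = _to_decimal(value[1])
        if lbs < 0 or oz < 0 or lbs + oz <= 0:
            raise ConversionError(f"non-positive mass: {value!r}")
        total = lbs * Decimal(MASS_FACTORS["lb"]) + oz * Decimal(MASS_FACTORS["oz"])
        return _truncate2(total), False
    return _convert(value, units, MASS_FACTORS, "mass")


@dataclass
class HarmonizedTraits:
    """The derived output fields appended to each occurrence record."""

    hasLength: bool = False
    hasMass: bool = False
    hasSex: bool = False
    hasLifeStage: bool = False
    lengthInMM: float | None = None
    massInG: float | None = None
    wereLengthUnitsInferred: bool = False
    wereMassUnitsInferred: bool = False
    derivedSex: str = ""
    derivedLifeStage: str = ""
    lengthType: str | None = None

    def as_row(self) -> dict:
        return {
            "hasLength": self.hasLength,
            "hasMass": self.hasMass,
            "hasSex": self.hasSex,
            "hasLifeStage": self.hasLifeStage,
            "lengthInMM": self.lengthInMM,
            "massInG": self.massInG,
            "wereLengthUnitsInferred": self.wereLengthUnitsInferred,
            "wereMassUnitsInferred": self.wereMassUnitsInferred,
            "derivedSex": self.derivedSex,
            "derivedLifeStage": self.derivedLifeStage,
            "lengthType": self.lengthType,
        }

    def check_invariants(self) -> None:
        assert not (self.lengthInMM is not None and not self.hasLength)
        assert not (self.massInG is not None and not self.hasMass)
        if self.lengthType and self.lengthType.endswith(" range"):
            assert self.lengthInMM is None and self.hasLength
        assert self.hasSex == bool(self.derivedSex)
        assert self.hasLifeStage == bool(self.derivedLifeStage)


def harmonize(
    record: OccurrenceRecord, extractions: Sequence[RawExtraction]
) -> HarmonizedTraits:
    """Assemble the harmonized trait fields for one record.

    The first length extraction (in the extraction order produced by
    ``extract_record``: field priority, then precedence tier, then leftmost
    span) supplies the scalar ``lengthInMM``; range extractions set
    ``lengthType`` to ``"<subtype> range"`` and leave ``lengthInMM`` absent.
    ``derivedSex`` prefers the Darwin Core ``sex`` field over the extracted
    value, and likewise for ``derivedLifeStage``; the ``has*`` flags reflect
    the derived fields, so a populated ``dwc:sex`` alone sets ``hasSex``.
    Conversion failures drop the offending extraction and leave the trait
    unset.
    """
    out = HarmonizedTraits()
    extracted_sex = ""
    extracted_stage = ""
    for ext in extractions:
        if ext.trait_type in LENGTH_SUBTYPES and not out.hasLength:
            if ext.is_range:
                out.hasLength = True
                out.lengthType = f"{ext.trait_type} range"
                out.wereLengthUnitsInferred = ext.units == "inferred"
            else:
                try:
                    mm, inferred = convert_length(ext.value, ext.units)
                except ConversionError as exc:
                    log.info("record %s: length dropped (%s)", record.record_id, exc)
                    continue
                out.hasLength = True
                out.lengthInMM = mm
                out.lengthType = ext.trait_type
                out.wereLengthUnitsInferred = inferred
        elif ext.trait_type == TRAIT_BODY_MASS and not out.hasMass:
            try:
                g, inferred = convert_mass(ext.value, ext.units)
            except ConversionError as exc:
                log.info("record %s: mass dropped (%s)", record.record_id, exc)
                continue
            out.hasMass = True
            out.massInG = g
            out.wereMassUnitsInferred = inferred
        elif ext.trait_type == TRAIT_SEX and not extracted_sex:
            extracted_sex = str(ext.value)
        elif ext.trait_type == TRAIT_LIFE_STAGE and not extracted_stage:
            extracted_stage = str(ext.value)

    out.derivedSex = record.sex_field.strip() or extracted_sex
    out.derivedLifeStage = record.life_stage_field.strip() or extracted_stage
    out.hasSex = bool(out.derivedSex)
    out.hasLifeStage = bool(out.derivedLifeStage)
    out.check_invariants()
    return out
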