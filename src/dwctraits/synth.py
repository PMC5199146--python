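"""Synthetic occurrence corpora with known ground truth.

The generator emulates the heterogeneity of digitized specimen remarks:
explicit "key: value" pairs, abbreviated keys, the mammalogy measurement
shorthand, length ranges, Imperial units, unitless values, and verbose
multi-individual remarks. Each record carries gold labels holding the true
harmonized values, so the whole pipeline can be tested end to end without
any external download.

True body lengths are drawn log-uniformly on 5-2000 mm and masses on
0.5-25000 g, reflecting the orders of magnitude body size spans across
vertebrates. The generator does not simulate typos or OCR noise; output is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .normalize import HarmonizedTraits, convert_length, convert_mass
from .records import OccurrenceRecord
from .validation import GoldLabel

STYLES = (
    "explicit_keyed",
    "abbreviated",
    "shorthand",
    "range",
    "imperial_units",
    "unitless",
    "verbose_multi_individual",
    "empty",
)

#: Styles on which extraction must recover ground truth exactly.
CLEAN_STYLES = (
    "explicit_keyed",
    "abbreviated",
    "shorthand",
    "range",
    "imperial_units",
)

#: (class, genus, epithet, length subtype pool)
_SPECIES = [
    ("Mammalia", "Tamias", "minimus", ("total length", "head-body length")),
    ("Mammalia", "Peromyscus", "maniculatus", ("total length", "head-body length")),
    ("Mammalia", "Sorex", "cinereus", ("total length",)),
    ("Aves", "Turdus", "migratorius", ("total length",)),
    ("Aves", "Zonotrichia", "leucophrys", ("total length",)),
    ("Reptilia", "Sceloporus", "undulatus", ("snout-vent length",)),
    ("Amphibia", "Lithobates", "pipiens", ("snout-vent length",)),
    ("Actinopterygii", "Micropterus", "salmoides", ("standard length", "fork length")),
    ("Actinopterygii", "Perca", "flavescens", ("standard length", "fork length")),
]

_ABBR = {
    "total length": "TL",
    "head-body length": "HB",
    "snout-vent length": "SVL",
    "standard length": "SL",
    "fork length": "FL",
}

_SEXES = ("male", "female")
_STAGES = ("adult", "juvenile", "subadult")


class MixError(ValueError):
    """Style mix weights are invalid."""


@dataclass(frozen=True)
class StyleMix:
    """Weights over generation styles, plus corpus size and seed."""

    weights: Mapping[str, float]
    seed: int = 0
    n: int = 100

    def __post_init__(self):
        unknown = set(self.weights) - set(STYLES)
        if unknown:
            raise MixError(f"unknown styles: {sorted(unknown)}")
        w = [self.weights.get(s, 0.0) for s in STYLES]
        if any(x < 0 for x in w):
            raise MixError("weights must be non-negative")
        if abs(sum(w) - 1.0) > 1e-9:
            raise MixError(f"weights must sum to 1, got {sum(w)}")
        if self.n < 0:
            raise MixError("n must be >= 0")

    def weight_vector(self) -> list[float]:
        return [self.weights.get(s, 0.0) for s in STYLES]


def clean_mix(seed: int = 0, n: int = 100) -> StyleMix:
    """Equal-weight mix over the five cleanly recoverable styles."""
    return StyleMix(
        weights={s: 1.0 / len(CLEAN_STYLES) for s in CLEAN_STYLES},
        seed=seed,
        n=n,
    )


@dataclass
class GoldRecord:
    """Ground truth for one synthetic record."""

    style: str
    expected: HarmonizedTraits
    #: traits whose rendering is keyless or ambiguous (excluded from
    #: confusion matrices, and not required to be extracted)
    ambiguous: frozenset[str] = field(default_factory=frozenset)


def _sample_length_mm(rng) -> float:
    return round(float(np.exp(rng.uniform(np.log(5.0), np.log(2000.0)))), 1)


def _sample_mass_g(rng) -> float:
    return round(float(np.exp(rng.uniform(np.log(0.5), np.log(25000.0)))), 1)


def _fmt(x: float) -> str:
    return f"{x:g}"


def _render(style: str, rng, subtype: str):  # noqa: C901
    """Render one record's free text; returns (text, expected, ambiguous)."""
    expected = HarmonizedTraits()
    ambiguous: set[str] = set()
    pieces: list[str] = []

    with_sex = style != "shorthand" and rng.random() < 0.7
    with_stage = style != "shorthand" and rng.random() < 0.7
    sex = str(rng.choice(_SEXES))
    stage = str(rng.choice(_STAGES))

    if style == "empty":
        return "", expected, frozenset()

    if style == "shorthand":
        total = int(rng.integers(60, 500))
        tail = int(rng.integers(10, max(11, int(total * 0.6))))  # tail < total
        hindfoot = int(rng.integers(5, 60))
        ear = int(rng.integers(5, 40))
        mass = _sample_mass_g(rng)
        pieces.append(f"{total}-{tail}-{hindfoot}-{ear}={_fmt(mass)}")
        expected.hasLength = True
        expected.lengthInMM = float(total)
        expected.lengthType = "total length"
        expected.wereLengthUnitsInferred = True
        expected.hasMass = True
        expected.massInG = mass
        expected.wereMassUnitsInferred = True
    elif style == "range":
        lo = int(rng.integers(5, 200))
        hi = lo + int(rng.integers(1, 100))
        pieces.append(f"{subtype}: {lo}-{hi} mm")
        expected.hasLength = True
        expected.lengthType = f"{subtype} range"
    else:
        length = _sample_length_mm(rng)
        mass = _sample_mass_g(rng)
        if style == "explicit_keyed":
            pieces.append(f"{subtype}: {_fmt(length)} mm")
            pieces.append(f"{rng.choice(['weight', 'body mass'])}: {_fmt(mass)} g")
            expected.lengthInMM, expected.massInG = length, mass
        elif style == "abbreviated":
            pieces.append(f"{_ABBR[subtype]}={_fmt(length)}")
            pieces.append(f"wt={_fmt(mass)}g")
            expected.lengthInMM, expected.massInG = length, mass
            expected.wereLengthUnitsInferred = True
        elif style == "imperial_units":
            inches = round(float(rng.uniform(1, 80)), 1)
            pieces.append(f"{subtype}: {_fmt(inches)} in")
            expected.lengthInMM = convert_length(inches, "in")[0]
            if rng.random() < 0.5:
                lbs, oz = int(rng.integers(1, 40)), int(rng.integers(1, 16))
                pieces.append(f"weight: {lbs} lbs {oz} oz")
                expected.massInG = convert_mass((lbs, oz), "lb+oz")[0]
            else:
                lbs_f = round(float(rng.uniform(0.2, 40)), 1)
                pieces.append(f"weight: {_fmt(lbs_f)} lbs")
                expected.massInG = convert_mass(lbs_f, "lbs")[0]
        elif style == "unitless":
            pieces.append(f"{subtype}: {_fmt(length)}")
            pieces.append(f"weight: {_fmt(mass)}")
            expected.lengthInMM, expected.massInG = length, mass
            expected.wereLengthUnitsInferred = True
            expected.wereMassUnitsInferred = True
        elif style == "verbose_multi_individual":
            k = int(rng.integers(2, 6))
            pieces.append(f"lot of {k} specimens, male and female")
            pieces.append(f"{subtype}: {_fmt(length)} mm")
            expected.lengthInMM = length
            ambiguous.add("sex")
            with_sex = False
        expected.hasLength = expected.lengthInMM is not None
        expected.hasMass = expected.massInG is not None
        if expected.hasLength:
            expected.lengthType = subtype

    if with_sex:
        pieces.append(rng.choice([f"sex: {sex}", f"sex={sex}"]))
        expected.hasSex = True
        expected.derivedSex = sex
    if with_stage:
        key = rng.choice(["life stage", "age class", "age"])
        pieces.append(f"{key}: {stage}")
        expected.hasLifeStage = True
        expected.derivedLifeStage = stage

    sep = str(rng.choice(["; ", ", ", " ; "]))
    return sep.join(pieces), expected, frozenset(ambiguous)


def generate_corpus(
    mix: StyleMix, lexicon=None
) -> tuple[list[OccurrenceRecord], dict[str, GoldRecord]]:
    """Generate ``mix.n`` records plus gold labels, deterministically.

    The ``lexicon`` argument is accepted for interface symmetry with the
    parsers; rendering uses the canonical default keys.
    """
    rng = np.random.default_rng(mix.seed)
    weights = mix.weight_vector()
    records: list[OccurrenceRecord] = []
    gold: dict[str, GoldRecord] = {}
    for i in range(mix.n):
        style = str(rng.choice(STYLES, p=weights))
        if style == "shorthand":
            cls, genus, epithet, subtypes = _SPECIES[int(rng.integers(0, 3))]
        else:
            cls, genus, epithet, subtypes = _SPECIES[
                int(rng.integers(0, len(_SPECIES)))
            ]
        subtype = str(rng.choice(list(subtypes)))
        text, expected, ambiguous = _render(style, rng, subtype)

        field_slot = int(rng.choice(3, p=[0.7, 0.2, 0.1]))
        rid = f"synth-{i:06d}"
        rec = OccurrenceRecord(
            record_id=rid,
            taxon_class=cls,
            genus=genus,
            specific_epithet=epithet,
            scientific_name=f"{genus} {epithet}",
        )
        if text:
            attr = ["dynamic_properties", "occurrence_remarks", "field_notes"]
            setattr(rec, attr[field_slot], text)
        records.append(rec)
        gold[rid] = GoldRecord(style=style, expected=expected, ambiguous=ambiguous)
    return records, gold


def gold_to_labels(
    gold: Mapping[str, GoldRecord]
) -> dict[str, dict[str, GoldLabel]]:
    """Convert gold records to per-trait validation labels."""
    out: dict[str, dict[str, GoldLabel]] = {}
    for rid, g in gold.items():
        e = g.expected
        out[rid] = {
            "length": GoldLabel(
                present=e.hasLength,
                value=e.lengthInMM,
                units="inferred" if e.wereLengthUnitsInferred else "mm",
                keyless_implied="length" in g.ambiguous,
            ),
            "mass": GoldLabel(
                present=e.hasMass,
                value=e.massInG,
                units="inferred" if e.wereMassUnitsInferred else "g",
                keyless_implied="mass" in g.ambiguous,
            ),
            "sex": GoldLabel(
                present=bool(e.derivedSex) or "sex" in g.ambiguous,
                value=e.derivedSex or None,
                keyless_implied="sex" in g.ambiguous,
            ),
            "life stage": GoldLabel(
                present=bool(e.derivedLifeStage),
                value=e.derivedLifeStage or None,
                keyless_implied="life stage" in g.ambiguous,
            ),
        }
    return out
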