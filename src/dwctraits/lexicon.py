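"""Trait lexicon and descriptor taxonomy.

The lexicon holds the canonical trait types (five body-length subtypes, body
mass, sex, life stage) together with the verbatim keys and abbreviations
publishers use for them. The descriptor taxonomy assigns free-text trait
descriptors (e.g. "tarsus length", "beak color") to a body region and to a
measurement-vs-qualitative mode, so that the heterogeneity of a corpus can
be summarized as a region-by-mode count matrix of distinct descriptors.

Synonym matching is case-insensitive and tolerant of separators: ``"_"``,
``"."``, ``"-"``, whitespace and camelCase boundaries are all equivalent, so
``totalLengthInMM``, ``total_length_in_mm`` and ``Total Length in MM`` all
name the same key.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

TRAIT_CLASSES = ("body_length", "body_mass", "sex", "life_stage")
LENGTH_SUBTYPES = (
    "total length",
    "head-body length",
    "snout-vent length",
    "standard length",
    "fork length",
)
REGIONS = (
    "head",
    "neck",
    "appendage",
    "tail",
    "trunk",
    "wholeOrg",
    "orgPartsComplex",
    "nonOrg",
    "other",
)
MODES = ("measurement", "qualitative")

#: Ontology identifiers recorded as fixed metadata (no term mapping is done).
VTO_BODY_LENGTH = "http://purl.obolibrary.org/obo/VT_0001256"
VTO_BODY_MASS = "http://purl.obolibrary.org/obo/VT_0001259"


class LexiconError(ValueError):
    """Lexicon configuration violates an invariant (e.g. synonym collision)."""


def normalize_synonym(text: str) -> str:
    """Collapse a synonym to its separator-free lowercase form.

    camelCase boundaries are split before lowercasing so ``ToL`` and
    ``totalLengthInMM`` normalize the same way their spaced forms do.
    """
    text = re.sub(r"(?<=[a-z])(?=[A-Z])", " ", text)
    return re.sub(r"[\s_.\-]+", "", text).lower()


@dataclass(frozen=True)
class LexiconEntry:
    """Canonical trait type plus the synonyms that name it."""

    canonical: str
    synonyms: frozenset[str]
    match_kind: str  # "explicit_key" | "abbreviation"
    trait_class: str

    def __post_init__(self):
        if self.match_kind not in ("explicit_key", "abbreviation"):
            raise LexiconError(f"bad match_kind: {self.match_kind!r}")
        if self.trait_class not in TRAIT_CLASSES:
            raise LexiconError(f"bad trait_class: {self.trait_class!r}")
        if self.trait_class == "body_length" and self.canonical not in LENGTH_SUBTYPES:
            raise LexiconError(
                f"body_length canonical must be one of {LENGTH_SUBTYPES}, "
                f"got {self.canonical!r}"
            )


@dataclass(frozen=True)
class DescriptorCategory:
    """A verbatim descriptor assigned to one (region, mode) pair."""

    descriptor: str
    region: str
    mode: str

    def __post_init__(self):
        if self.region not in REGIONS:
            raise LexiconError(f"bad region: {self.region!r}")
        if self.mode not in MODES:
            raise LexiconError(f"bad mode: {self.mode!r}")


def _data_text(name: str) -> str:
    return resources.files("dwctraits.data").joinpath(name).read_text("utf-8")


def _entries_from_config(config: Mapping) -> list[LexiconEntry]:
    entries = []
    for trait_class, canonicals in config.items():
        if trait_class not in TRAIT_CLASSES:
            raise LexiconError(f"unknown trait class: {trait_class!r}")
        for canonical, kinds in (canonicals or {}).items():
            kinds = kinds or {}
            for kind_key, match_kind in (
                ("explicit", "explicit_key"),
                ("abbreviations", "abbreviation"),
            ):
                syns = kinds.get(kind_key) or []
                if syns:
                    entries.append(
                        LexiconEntry(
                            canonical=canonical,
                            synonyms=frozenset(str(s) for s in syns),
                            match_kind=match_kind,
                            trait_class=trait_class,
                        )
                    )
    return entries


def _check_collisions(entries: Iterable[LexiconEntry]) -> None:
    # Uniqueness is required across entries of a trait class after
    # normalization; variants within one canonical that normalize
    # identically are harmless spelling alternatives.
    seen: dict[tuple[str, str], str] = {}
    for entry in entries:
        for syn in entry.synonyms:
            key = (entry.trait_class, normalize_synonym(syn))
            owner = seen.get(key)
            if owner is not None and owner != entry.canonical:
                raise LexiconError(
                    f"synonym {syn!r} appears under both {owner!r} and "
                    f"{entry.canonical!r} in trait class {entry.trait_class!r}"
                )
            seen[key] = entry.canonical


def load_lexicon(config: str | Path | None = None) -> list[LexiconEntry]:
    """Load the trait lexicon, merging a user config over the defaults.

    The user config is YAML with the same schema as the built-in file; any
    trait class it leaves out, or leaves empty, falls back to the default
    entries for that class.

    Raises
    ------
    LexiconError
        If a synonym appears under two canonicals within one trait class.
    """
    default = yaml.safe_load(_data_text("lexicon.yaml"))
    if config is not None:
        user = yaml.safe_load(Path(config).read_text("utf-8")) or {}
        merged = dict(default)
        for trait_class, section in user.items():
            if section:  # empty section -> fall back to default
                merged[trait_class] = section
        default = merged
    entries = _entries_from_config(default)
    _check_collisions(entries)
    return entries


def load_descriptor_taxonomy(
    config: str | Path | None = None,
) -> list[DescriptorCategory]:
    """Load the descriptor taxonomy (defaults, optionally extended)."""
    mapping = yaml.safe_load(_data_text("descriptors.yaml"))
    if config is not None:
        mapping.update(yaml.safe_load(Path(config).read_text("utf-8")) or {})
    out = []
    for descriptor, (region, mode) in mapping.items():
        out.append(DescriptorCategory(descriptor=descriptor, region=region, mode=mode))
    return out


def categorize_descriptors(
    descriptors: Iterable[str],
    taxonomy: Iterable[DescriptorCategory],
) -> pd.DataFrame:
    """Count distinct descriptors per (region, mode).

    Returns a region x mode DataFrame of distinct-descriptor counts; repeated
    occurrences of one descriptor count once. Descriptors missing from the
    taxonomy land in the ``other`` region (their mode guessed as qualitative)
    and are logged.
    """
    lookup = {normalize_synonym(c.descriptor): c for c in taxonomy}
    matrix = pd.DataFrame(0, index=list(REGIONS), columns=list(MODES), dtype=int)
    unmatched = []
    for desc in sorted({normalize_synonym(d) for d in descriptors if d.strip()}):
        cat = lookup.get(desc)
        if cat is None:
            unmatched.append(desc)
            matrix.loc["other", "qualitative"] += 1
        else:
            matrix.loc[cat.region, cat.mode] += 1
    if unmatched:
        log.info("%d descriptors not in taxonomy -> 'other': %s",
                 len(unmatched), unmatched)
    return matrix
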