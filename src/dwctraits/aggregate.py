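"""Clade assignment, species-name derivation and trait-coverage summaries.

Coverage is reported as the number of distinct species names per clade
whose record tally with a given trait meets each of three thresholds: at
least 1 record, more than 10, and more than 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .normalize import HarmonizedTraits
from .records import OccurrenceRecord

log = logging.getLogger(__name__)

CLADES = ("Fish", "Amphibia", "Reptilia", "Aves", "Mammalia",
          "Non_vertebrates", "Unknown")

#: Taxonomic classes pooled into the Fish clade.
FISH_CLASSES = {
    "actinopterygii", "cephalaspidomorphi", "chondrichthyes",
    "elasmobranchii", "holocephali", "leptocardii", "myxini",
    "petromyzonti", "sarcopterygii",
}

VERTEBRATE_CLASSES = {
    "amphibia": "Amphibia",
    "reptilia": "Reptilia",
    "aves": "Aves",
    "mammalia": "Mammalia",
}

#: Illustrative non-vertebrate classes; config-extensible.
NON_VERTEBRATE_CLASSES = {
    "insecta", "arachnida", "malacostraca", "branchiopoda", "maxillopoda",
    "gastropoda", "bivalvia", "cephalopoda", "polyplacophora",
    "anthozoa", "hydrozoa", "scyphozoa", "asteroidea", "echinoidea",
    "holothuroidea", "clitellata", "polychaeta", "diplopoda", "chilopoda",
}

#: Collection-metadata tags that imply a clade when dwc:class is empty.
CONTEXT_CLADES = {
    "ornithology": "Aves",
    "mammalogy": "Mammalia",
    "ichthyology": "Fish",
    "birds": "Aves",
    "mammals": "Mammalia",
    "fishes": "Fish",
}

THRESHOLDS = (">=1", ">10", ">100")
COVERAGE_TRAITS = ("length", "mass", "sex", "life stage")


def assign_clade(record: OccurrenceRecord) -> str:
    """Map a record to a clade bucket from dwc:class or collection context."""
    cls = record.taxon_class.strip().lower()
    if cls:
        if cls in FISH_CLASSES:
            return "Fish"
        if cls in VERTEBRATE_CLASSES:
            return VERTEBRATE_CLASSES[cls]
        if cls in NON_VERTEBRATE_CLASSES:
            return "Non_vertebrates"
        log.debug("unrecognized class %r -> Unknown", record.taxon_class)
        return "Unknown"
    context = (record.collection_context or "").strip().lower()
    return CONTEXT_CLADES.get(context, "Unknown")


def derive_species_name(record: OccurrenceRecord) -> str | None:
    """Species name from genus+specificEpithet, else scientificName.

    Rule (i): concatenate ``dwc:genus`` and ``dwc:specificEpithet`` when
    both are non-empty; rule (ii): the first two whitespace-separated words
    of ``dwc:scientificName``; otherwise absent.
    """
    genus = record.genus.strip()
    epithet = record.specific_epithet.strip()
    if genus and epithet:
        return f"{genus} {epithet}"
    words = record.scientific_name.split()
    if len(words) >= 2:
        return f"{words[0]} {words[1]}"
    return None


@dataclass
class CladeSummary:
    """Distinct-species counts per trait and record-count threshold."""

    clade: str
    species_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def check_invariants(self) -> None:
        for per_trait in self.species_counts.values():
            counts = [per_trait[t] for t in THRESHOLDS]
            assert counts[0] >= counts[1] >= counts[2]


def _trait_present(traits: HarmonizedTraits, trait: str) -> bool:
    return {
        "length": traits.hasLength,
        "mass": traits.hasMass,
        "sex": traits.hasSex,
        "life stage": traits.hasLifeStage,
    }[trait]


def summarize_coverage(
    pairs: Iterable[tuple[OccurrenceRecord, HarmonizedTraits]],
) -> dict[str, CladeSummary]:
    """Count distinct species names meeting each record-count threshold.

    A species split across two clades (a data error upstream) is counted in
    each clade independently. Records without a derivable species name are
    skipped.
    """
    # (clade, trait, species) -> record tally
    tallies: dict[tuple[str, str, str], int] = {}
    for record, traits in pairs:
        species = derive_species_name(record)
        if species is None:
            continue
        clade = assign_clade(record)
        for trait in COVERAGE_TRAITS:
            if _trait_present(traits, trait):
                key = (clade, trait, species)
                tallies[key] = tallies.get(key, 0) + 1

    summaries = {
        clade: CladeSummary(
            clade=clade,
            species_counts={
                trait: {t: 0 for t in THRESHOLDS} for trait in COVERAGE_TRAITS
            },
        )
        for clade in CLADES
    }
    for (clade, trait, _species), n in tallies.items():
        counts = summaries[clade].species_counts[trait]
        counts[">=1"] += 1
        if n > 10:
            counts[">10"] += 1
        if n > 100:
            counts[">100"] += 1
    for summary in summaries.values():
        summary.check_invariants()
    return summaries


def coverage_table(summaries: dict[str, CladeSummary]) -> pd.DataFrame:
    """Per-clade coverage as a DataFrame with a Total row.

    Columns are a (trait, threshold) MultiIndex; the Total row is the sum
    over clades (species repeated across clades count once per clade).
    """
    rows = {}
    for clade in CLADES:
        s = summaries[clade]
        rows[clade] = {
            (trait, thr): s.species_counts[trait][thr]
            for trait in COVERAGE_TRAITS
            for thr in THRESHOLDS
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["trait", "threshold"])
    frame.loc["Total"] = frame.sum(axis=0)
    return frame
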