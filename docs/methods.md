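# Methods

## The extraction problem

Specimen occurrence records published in Darwin Core carry body
measurements almost exclusively as free text in three generic fields —
`dynamicProperties` (intended for attribute-value content),
`occurrenceRemarks` and `fieldNotes`. There is no enforced syntax: the same
total length may appear as `total length: 230 mm`, `TL 230`,
`totalLengthInMM=230`, or as the first element of the mammalogy shorthand
`230-95-30-20 = 71.9`. dwctraits treats extraction as deterministic,
ordered pattern matching rather than statistical NLP: the vocabulary is
small and closed (a lexicon of trait keys and abbreviations), the cost of a
false positive in a published aggregate is high, and rule behavior must be
auditable case by case.

## Candidate filtering

A record is a candidate when any of the three free-text fields is
non-empty. Because CSV exports serialize database NULLs inconsistently,
the tokens `""`, `NA` and `NULL` (any case, after trimming) all count as
empty. Filtering preserves order and is idempotent.

## Trait model

Four trait classes are extracted:

- **body length**, subtyped into the five community measurement
  conventions: *total length* (birds, mammals, general), *head-body
  length* (mammals), *snout-vent length* (reptiles and amphibians),
  *standard length* and *fork length* (fishes). The subtype is part of the
  output (`lengthType`), because the conventions are not interconvertible.
- **body mass**, a single type; all synonyms (weight, wt, mass, …) map to it.
- **sex** and **life stage**, categorical attributes kept verbatim — no
  vocabulary normalization is applied to their values.

## Matching rules and false-positive guards

Per trait type and field, the tiers run: explicit key with units, explicit
key without units, abbreviation with an adjacent numeric (within three
characters), then shorthand. Earlier tiers claim character spans; later
matches overlapping a claimed span are discarded, as is any second match
for a type already taken (ties break leftmost). Matching is
case-insensitive, word-boundary anchored, and separator-tolerant
(`_`, `.`, `-`, spaces and camelCase boundaries are equivalent), so
`totalLengthInMM` matches the key "total length in mm"; keys that name
their own units override the inferred-units default.

Specific guards, each trading recall for precision:

- Generic one-word keys (`length`, `weight`, `mass`) are rejected when
  immediately preceded by another word, so `tail length 30 mm` does not
  become a total length.
- The unit token `in` is accepted only when not followed by further prose
  (`10 in` at a delimiter is inches; `10 in the stream` is skipped
  entirely rather than guessed).
- Shorthand requires 3–5 dash-separated numerics; a three-part chain with a
  four-digit year-like component or leading zeros (`12-05-2003`) is
  rejected as a date. Only the first numeric (total length) and the
  post-`=` numeric (mass) are emitted; tail, hind foot and ear are matched
  but never output, since the output schema is scalar per trait.
- Sex is extracted when keyed (`sex=F`) or as an isolated bare
  `male`/`female` token; single letters require a key. If one field
  contains conflicting sex tokens (verbose remarks about multi-individual
  lots), nothing is emitted for that field.
- Life stage requires a key (`life stage:`, `age class:`, `age:`) in
  default mode; bare stage words (`adult`) are known to be common but are
  deliberately not extracted, since without a key the assignment is a
  guess. An opt-in aggressive mode extracts them flagged `keyless`.
- Decimal commas (`71,9`) are accepted and normalized at conversion time;
  the stored extraction value stays verbatim so provenance (span, substring
  identity) is exact.

Fields are visited in the order `dynamicProperties`, `occurrenceRemarks`,
`fieldNotes` — the first is designed to hold attribute-value content and in
practice dominates — and per trait type the first field that yields a match
wins. When several length subtypes occur in one record, the scalar
`lengthInMM` comes from the first extraction in (field, tier, position)
order; the others are visible through the extraction API but not in the
harmonized scalar schema.

## Unit standardization

Lengths convert to millimeters (cm×10, m×1000, in×25.4, ft×304.8) and
masses to grams (kg×1000, lb×453.59237, oz×28.349523125; `X lb Y oz`
compounds sum their components). Measurements written without units are
assumed mm/g — the community custom, certain for shorthand, less certain
elsewhere — and flagged `were*UnitsInferred`. Converted values are
**truncated** (not rounded) to two decimal places; inputs reported at lower
precision keep their precision. Arithmetic uses `decimal.Decimal` so
truncation acts on decimal digits, not on binary float representations.
Non-positive values and unknown unit tokens reject the extraction (logged;
the trait is left unset). No plausibility bounds are applied — an 8 m
"total length" passes; outlier screening is downstream analysis.

Length ranges (`standard length: 20–35 mm`) almost always describe
multi-specimen lots, so no midpoint is invented: the record gets
`hasLength=true`, `lengthType="standard length range"`, and no
`lengthInMM`. Mass ranges are not produced at all.

## Derived fields

`derivedSex` is the Darwin Core `sex` field when non-empty, else the
extracted sex; `derivedLifeStage` analogously. The `has*` flags follow the
derived fields, so a populated `dwc:sex` alone sets `hasSex` — the flags
drive search filters over the combined content, not extraction accounting.

## Validation

Extractions are scored per trait against gold labels: TP requires presence
and, for measurements, exact value equality after truncation (an extracted
but wrong value counts as a commission error, FP). Gold entries flagged
*keyless-implied* — values no key ties to a trait — are tallied separately
and excluded from the matrix, since neither extracting nor skipping them is
unambiguously right. TPR = TP/(TP+FN), TNR = TN/(TN+FP), and MCC with the
convention that a zero denominator factor yields 0; metrics are reported to
three decimals. Validation sampling reproduces the manual procedure
literally: attach a column of seeded random numbers, sort, take the first
*n*.

## Aggregation

Clades derive from `dwc:class` (case-insensitive exact match; nine
fish-like classes pool into *Fish*; a small extensible list of invertebrate
classes maps to *Non_vertebrates*; unrecognized or missing classes fall
back to collection metadata such as "ornithology" → Aves, else *Unknown*).
Species names use genus+epithet, falling back to the first two
whitespace-separated words of `scientificName` (punctuation retained).
Coverage counts distinct species names per clade and trait at thresholds
≥1, >10 and >100 records; a species split across clades by upstream data
errors counts in each clade independently.

## Synthetic corpus

The generator emulates the documented heterogeneity in eight styles:
explicit keyed text, abbreviations, mammal shorthand, length ranges,
Imperial units, unitless values, verbose multi-individual remarks, and
empty records. True lengths are log-uniform on 5–2000 mm and masses on
0.5–25000 g (body size spans orders of magnitude); shorthand middle values
keep tail < total length per mammal convention; species and classes come
from a small fixed pool spanning all five vertebrate clades; the text lands
in one of the three fields with probabilities 0.7/0.2/0.1. Everything is
deterministic under a fixed seed.

The generator renders canonical spellings plus the abbreviation variants —
it does not simulate typos, OCR noise, over-precise decimals, or the long
tail of publisher idiosyncrasies. Exact recovery on the clean styles
therefore demonstrates the pipeline's correctness on well-formed input and
its guards on the adversarial styles generated; it does not bound error
rates on real corpora, which must come from manual validation samples.

## Problem sizes and numerical choices

The end-to-end recovery check runs on a 10,000-record corpus mixed equally
over the five clean styles — large enough to exercise every rendering
branch hundreds of times while keeping the suite fast. The MCC property
suite compares 1,000 random confusion matrices against a brute-force
Pearson correlation of the equivalent binary vectors (tolerance 1e-9).
Byte-stable output uses minimal decimal serialization (235.0 → "235",
booleans as "true"/"false", absent numerics as empty strings).

## Known limitations

- Darwin Core Archive support is read-only and limited to the occurrence
  core; extensions are ignored with a warning, and archives are never
  written.
- `dynamicProperties` content that is itself structured (JSON-like) is
  treated as an opaque string.
- The shipped lexicon and descriptor taxonomy are representative, not
  exhaustive; both are config-extensible (YAML overlay per trait class).
- Inferred units are always mm/g; a kilogram-scale shorthand for megafauna
  would be misread by design.
- No taxonomic name resolution or synonymy: species counts are counts of
  name strings.
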