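# Default trait lexicon: canonical trait types, their explicit keys and
# abbreviations, grouped by trait class.
#
# Schema:
#   <trait_class>:
#     <canonical trait type>:
#       explicit: [list of multi-word keys]
#       abbreviations: [list of short forms requiring an adjacent numeric]
#
# Synonym matching downstream is case-insensitive and tolerant of
# separators ("_", ".", camelCase), so "totalLengthInMM" matches
# "total length in mm".
body_length:
  total length:
    explicit:
      - total length
      - total length in mm
      - total length in millimeters
      - length
      - body length
      - max length
      - meas
    abbreviations:
      - TL
      - ToL
      - T.L.
  head-body length:
    explicit:
      - head-body length
      - head body length
      - head-body length in mm
      - head and body length
    abbreviations:
      - HB
  snout-vent length:
    explicit:
      - snout-vent length
      - snout vent length
      - snout-vent length in mm
      - snoutvent length
    abbreviations:
      - SVL
      - S.V.L.
  standard length:
    explicit:
      - standard length
      - standard length in mm
    abbreviations:
      - SL
  fork length:
    explicit:
      - fork length
      - fork length in mm
    abbreviations:
      - FL
body_mass:
  body mass:
    explicit:
      - body mass
      - body weight
      - weight
      - weight in g
      - weight in grams
      - weight in lbs
      - mass
      - mass in g
      - mass in grams
      - observed weight
      - dead weight
    abbreviations:
      - wt
      - wt.
      - w.t.
sex:
  sex:
    explicit:
      - sex
    abbreviations: []
life_stage:
  life stage:
    explicit:
      - life stage
      - lifestage
      - age class
      - age
      - stage
    abbreviations: []
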