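# Default descriptor taxonomy: verbatim trait descriptors found in
# dynamicProperties-style content, each assigned one body region and one
# mode (measurement vs qualitative). A representative subset; extensible
# via user config.
#
# Schema:  <descriptor>: [<region>, <mode>]
# Regions: head, neck, appendage, tail, trunk, wholeOrg, orgPartsComplex,
#          nonOrg, other
# Modes:   measurement, qualitative
bill length: [head, measurement]
culmen length: [head, measurement]
bill depth: [head, measurement]
bill width: [head, measurement]
head length: [head, measurement]
head width: [head, measurement]
skull length: [head, measurement]
ear length: [head, measurement]
ear from notch: [head, measurement]
eye diameter: [head, measurement]
beak color: [head, qualitative]
bill color: [head, qualitative]
eye color: [head, qualitative]
iris color: [head, qualitative]
crown color: [head, qualitative]
neck length: [neck, measurement]
neck girth: [neck, measurement]
throat color: [neck, qualitative]
wing chord: [appendage, measurement]
wing length: [appendage, measurement]
wingspan: [appendage, measurement]
tarsus length: [appendage, measurement]
hind foot length: [appendage, measurement]
hind foot with claw: [appendage, measurement]
forearm length: [appendage, measurement]
flipper length: [appendage, measurement]
fin length: [appendage, measurement]
claw length: [appendage, measurement]
wing color: [appendage, qualitative]
foot color: [appendage, qualitative]
leg color: [appendage, qualitative]
tail length: [tail, measurement]
tail vertebrae count: [tail, measurement]
tail fork depth: [tail, measurement]
tail color: [tail, qualitative]
tail condition: [tail, qualitative]
girth: [trunk, measurement]
chest girth: [trunk, measurement]
gonad length: [trunk, measurement]
gonad width: [trunk, measurement]
testis length: [trunk, measurement]
ovary length: [trunk, measurement]
clutch size: [trunk, measurement]
egg count: [trunk, measurement]
fat deposits: [trunk, qualitative]
reproductive condition: [trunk, qualitative]
gonad condition: [trunk, qualitative]
plumage: [trunk, qualitative]
pelage color: [trunk, qualitative]
total length: [wholeOrg, measurement]
standard length: [wholeOrg, measurement]
fork length: [wholeOrg, measurement]
total body weight: [wholeOrg, measurement]
body condition: [wholeOrg, qualitative]
coloration: [wholeOrg, qualitative]
molt status: [wholeOrg, qualitative]
snout-vent length: [orgPartsComplex, measurement]
head-body length: [orgPartsComplex, measurement]
head and neck color: [orgPartsComplex, qualitative]
nest height: [nonOrg, measurement]
nest material: [nonOrg, qualitative]
habitat description: [nonOrg, qualitative]
stomach contents: [other, qualitative]
parasite load: [other, measurement]
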