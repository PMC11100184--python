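# Default enzyme-family map for the L-ascorbate (vitamin C) biosynthesis
# screen: the 18 families spanning the L-galactose, galacturonate,
# L-gulose and myo-inositol routes plus the ascorbate recycling enzymes.
#
# Each family matches by KEGG Orthology identifier and/or by a
# case-insensitive whole-word keyword against the annotation description.
# KO identifiers are the canonical KEGG orthologies for each enzyme; the
# map is a plain config file and is meant to be edited per genome.
#
# "DHA" is accepted as an alias of DHAR (dehydroascorbate reductase).
HK:
  kos: [K00844]
  keywords: [hexokinase]
PGI:
  kos: [K01810]
  keywords: [glucose-6-phosphate isomerase]
PMI:
  kos: [K01809]
  keywords: [mannose-6-phosphate isomerase]
PMM:
  kos: [K17497]
  keywords: [phosphomannomutase]
GMP:
  kos: [K00966]
  keywords: [mannose-1-phosphate guanylyltransferase, GDP-mannose pyrophosphorylase]
GME:
  kos: [K10046]
  keywords: [GDP-mannose 3',5'-epimerase]
GGP:
  kos: [K14190]
  keywords: [GDP-L-galactose phosphorylase]
GPP:
  kos: [K22131]
  keywords: [L-galactose 1-phosphate phosphatase]
GDH:
  kos: [K19853]
  keywords: [L-galactose dehydrogenase, L-galactose 1-dehydrogenase]
GLDH:
  kos: [K00225]
  keywords: [galactono-1,4-lactone dehydrogenase]
MDHAR:
  kos: [K08232]
  keywords: [monodehydroascorbate reductase]
DHAR:
  kos: [K08233]
  keywords: [dehydroascorbate reductase]
  aliases: [DHA]
APX:
  kos: [K00434]
  keywords: [ascorbate peroxidase]
GalUR:
  kos: [K00041]
  keywords: [galacturonate reductase, galacturonic acid reductase]
GulLO:
  kos: [K00103]
  keywords: [gulonolactone oxidase]
ALase:
  kos: []
  keywords: [aldonolactonase]
GulDH:
  kos: []
  keywords: [gulonate dehydrogenase, gulose dehydrogenase]
MIOX:
  kos: [K00469]
  keywords: [inositol oxygenase]
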