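# Cross-database harmonization of carcinogenicity call encodings.
# CPDBAS-style ActivityOutcome strings and ISSCAN-style numeric Canc codes
# map onto one POSITIVE / EQUIVOCAL / NEGATIVE scale. Equating "unspecified"
# with the numeric equivocal code is this map's documented choice.
ActivityOutcome:
  active: POSITIVE
  unspecified: EQUIVOCAL
  inactive: NEGATIVE
Canc:
  "3": POSITIVE
  "2": EQUIVOCAL
  "1": NEGATIVE
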