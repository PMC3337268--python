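# Default conversion ruleset for the bundled toxml-mini schema.
#
# containers: wrapper elements elided during conversion (each Test/Compound
#   is an independent object in OWL, related to its originating class).
# renames: the Results field is used in several contexts; in the treatment
#   group it is renamed to TreatmentResults.
# promotions: enumerated or expert-listed string leaves lifted to classes so
#   their values become named concepts (Sex instead of a free string).
# subclasses: the only IS-A axioms emitted; the converted structure is flat.
base_iri: http://example.org/toxlift/toxml
containers:
  - Tests
  - Compounds
renames:
  ToxML/Study/Tests/Test/TreatmentGroup/Results: TreatmentResults
promotions:
  - ToxML/Study/Tests/Test/TestAnimal/Sex
subclasses:
  - [ChronicStudies, Study]
unify: {}
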