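# toxlift

Predictive toxicology needs structured, semantically annotated data, but the
field's working assets are not structured that way: study schemas are deeply
nested XML, and public carcinogenicity collections ship as SDF files whose
data fields are documented only in prose. `toxlift` is a small toolchain that
bridges that gap:

* **Schema lifting** — parse a ToxML-style XSD subset into a field graph and
  convert it, under a declarative ruleset, into a flat OWL-DL ontology:
  every nested field pair (F₁ ⊃ F₂) becomes classes `F1`, `F2` plus an
  object property `hasF2` with `rdfs:domain F1` and `rdfs:range F2` (a union
  of classes when `F2` nests under several parents); string leaves become
  `hasX` datatype properties; enumerated leaves are promoted to classes;
  wrapper containers (`Tests`, `Compounds`) are elided; IS-A axioms appear
  only where explicitly asserted (e.g. `ChronicStudies ⊑ Study`).
* **Vocabulary fixtures** — deterministic builders for a toxicological
  endpoint ontology (carcinogenicity, *in vitro* / *in vivo* mutagenicity,
  repeated-dose and aquatic toxicity, test systems, test results) and an
  organs-and-effects ontology (13 rodent organ systems, anatomical
  structures, and the effect → pathological effect → diagnostic feature
  chain), shipped as byte-stable Turtle/OWL files.
* **Value normalization** — typed parsing of heterogeneous indicator
  strings: survival ratios such as `0/5 (weeks 27-30)` or `16/17`, and
  qualitative phrases such as `MORTALITY, INCREASED`.
* **Dataset annotation & harmonization** — read SDF datasets into an
  OpenTox-style `ot:Dataset`/`ot:Feature`/`ot:FeatureValue` RDF model,
  attach `owl:sameAs` / `rdf:type` links into the vocabularies, and map
  divergent carcinogenicity call encodings (`ActivityOutcome` strings vs
  numeric `Canc` codes) onto one POSITIVE / EQUIVOCAL / NEGATIVE scale so
  several databases can be queried as one.

It is intended for tool builders and data curators in computational
toxicology who need schemas and datasets lifted into RDF reproducibly —
all serializations are canonical (sorted triples, no blank nodes), so
identical inputs give identical bytes.

## Worked example

```python
import toxlift as tx

graph = tx.parse_schema(tx.load_text("toxml_mini"))
rules = tx.load_ruleset(tx.load_text("default_rules"))
model, report = tx.convert(graph, rules)

print(sorted(model.classes))
prop = model.object_properties["hasTest"]
print(prop.domain, "->", prop.range)
print(model.subclass_axioms)
```

prints

```
['Background', 'ChronicStudies', 'Compound', 'ReferenceCompound', 'Results',
 'Sex', 'Study', 'Test', 'TestAnimal', 'ToxML', 'TreatmentGroup', 'TreatmentResults']
('ChronicStudies', 'Study') -> ('Test',)
{('ChronicStudies', 'Study')}
```

The 27 schema fields produced 12 classes: the `Tests`/`Compounds` wrappers
were elided, `Test` (which nests under both `Study` and `ChronicStudies`)
became a single class whose incoming `hasTest` property carries a union
domain, the enumerated `Sex` leaf was promoted to a class, and the ambiguous
treatment-group `Results` field was renamed `TreatmentResults`. The only
subclass axiom is the asserted `ChronicStudies ⊑ Study`.

Harmonized querying across the two toy SDF dialects:

```python
cpdbas = tx.build_dataset(tx.read_sdf(tx.load_text("cpdbas_toy")),
                          "http://example.org/ds/cpdbas",
                          call_feature="ActivityOutcome")
isscan = tx.build_dataset(tx.read_sdf(tx.load_text("isscan_toy")),
                          "http://example.org/ds/isscan", call_feature="Canc")
print(tx.query_merged([cpdbas, isscan], call="POSITIVE"))
```

prints `['CPD-001', 'CPD-002', 'ISS-001']` — the two `active` compounds and
the one `Canc=3` compound, answered as a single positive set.

The same pipeline is available from the shell:

```bash
toxlift convert src/toxlift/data/toxml_mini.xsd --out toxml.ttl
toxlift fixtures --out ontologies/
toxlift harmonize-query src/toxlift/data/cpdbas_toy.sdf \
    src/toxlift/data/isscan_toy.sdf \
    --call-feature ActivityOutcome --call-feature Canc --call POSITIVE
toxlift parse-values "0/5 (weeks 27-30)" "16/17"
```

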