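# Methods

## Problem and model

Toxicity study schemas in the ToxML style encode their domain model as deep
XML nesting: a `Study` contains a `Background`, which contains a
`ReferenceCompound`, and so on. Nesting expresses *association*, not
specialization, so a faithful ontological reading is flat: each complex
field is a class, and each nesting tuple (F₁ ⊃ F₂) is an object property
`hasF2` with domain F₁ and range F₂. Subclass (IS-A) axioms are emitted only
where a curator asserts them, because XML containment carries no taxonomic
meaning. The output stays inside a deliberately small OWL-DL fragment —
named classes, object/datatype properties with (possibly union) domains and
ranges, subclass axioms, comments — with no cardinality restrictions and no
anonymous class expressions beyond named `owl:unionOf` helpers.

## Schema parsing

`parse_schema` supports a fixed XSD subset: `xs:element` (inline anonymous
types or references to named global `complexType`/`simpleType`),
`xs:sequence` and `xs:choice` (both read as plain nesting — ordering carries
no meaning for the conversion), `xs:restriction` with string `xs:enumeration`
facets, and `minOccurs`/`maxOccurs`. Anything else is a hard error naming
the construct and path: the converter must account for every field, so a
silently skipped construct would corrupt the accounting. Named global types
are expanded at each point of use, giving one field per *use site*, keyed by
its path from the document root; a synthetic document-level node holds the
top-level elements. `minOccurs` is recorded but unused; `maxOccurs > 1` is
recorded for reporting only — no cardinality axioms are emitted. Imports and
includes are not supported; a schema is assumed self-contained.

## Conversion rules

Rules are declarative (`RuleSet`, loadable from YAML) because schema
semantics are a curation decision, not something inferable from structure:

* **containers** (default `Tests`, `Compounds`): wrapper elements elided;
  their children re-attach to the wrapper's parent. A structural heuristic
  (wrapper whose sole child is a repeated complex element with the singular
  name) exists behind `container_heuristic` but is off by default — explicit
  listing wins. Matching is by name or full path, and only complex fields
  can match.
* **renames** (path → label): disambiguate a name that means different
  things in different contexts (the treatment-group `Results` becomes
  `TreatmentResults`). `ambiguous_names` lists the candidates.
* **promotions**: string leaves lifted to classes so their values become
  named concepts. Promotion triggers on an enumeration facet *or* explicit
  listing; free-text strings are never promoted implicitly.
* **unify** (label → label): sanctioned merges of differently named fields.
* **subclasses**: the only source of IS-A axioms.

Classes are deduplicated by final (post-rename, post-unify) label: the same
name reused for the same concept under several parents (e.g. `Test`)
becomes one class, and the single incoming `has<Label>` property takes the
union of the parents as its domain. Label use is kept coherent: if a name
denotes a class anywhere in the schema, leaf occurrences of that name are
treated as the class too, so no IRI is ever declared both an object and a
datatype property. A rename or unification that makes two *differently*
named fields collide without a sanctioning `unify` entry is an error listing
both paths. The `ConversionReport` assigns every input path exactly one
disposition (`class`, `object_property_range`, `datatype_property`,
`promoted_class`, `elided_container`), so the rule application is total by
construction and checked by fuzz tests.

## Serialization and consistency checking

Identical models must produce identical bytes, so Turtle output is written
by a sorted-triple emitter (one triple per line, rdflib's term writer for
escaping, lexicographic order) rather than a general-purpose serializer
whose output order is unspecified. All nodes are IRIs — union classes and
their RDF list cells get deterministic names — which makes graph comparison
set equality and keeps round-trips exact. RDF/XML output feeds triples to
the standard serializer in canonical order. `n3` output shares the Turtle
writer (Turtle is a subset of N3).

Description-logic reasoning is replaced by structural checks
(`check_structure`): dangling domain/range/subclass references, subclass
cycles, malformed labels, class/property and object/datatype label clashes.
This is sufficient because the emitted fragment contains no constructs that
would require tableau reasoning; it is a documented limitation for
ontologies imported from elsewhere.

## Vocabulary fixtures

The endpoint ontology fixes the study-type vocabulary (five study types,
with chronic / sub-chronic / sub-acute under repeated-dose), test-system
terms (strain, species, sex, route of exposure) and test-result terms
(toxicity measure, test call, mode of action, target site). The
organs-and-effects ontology fixes the 13 organ systems — multi-word names
become camel-case labels with the full phrase kept as an `rdfs:comment` for
terminology fidelity — plus a scaffold of anatomical structures, cell types
and hormones/enzymes with demo content for the respiratory and digestive
tracts, and the effect → pathological effect → diagnostic feature property
chain. Both are vocabulary scaffolds: the anatomical and lesion content is
illustrative, not a nomenclature reproduction, and species specificity is
marked only by a rodent-focus annotation. The shipped `.ttl`/`.owl` files
are regenerated by `toxlift fixtures` and tested byte-identical to fresh
builds.

## Value normalization

`parse_ratio` implements the grammar `INT "/" INT ["(weeks" INT "-" INT ")"]`
with flexible whitespace and a case-insensitive `weeks` keyword (the one
dialect observed in chronic-study records). Syntax errors and domain errors
are distinct: `6/5` (more survivors than tested), a zero denominator, or an
inverted or zero-based week range match the grammar but are data problems.
Whether a week window qualifies deaths within it or survival measured at its
end is not defined by the sources, so the record stores the interval without
interpretation. Out-of-grammar values are not dropped downstream: the CLI
carries them verbatim with a warning flag, because inconsistent records are
part of the data. `parse_effect` splits `"MORTALITY, INCREASED"`-style
phrases on the last comma and maps direction synonyms onto the closed set
{INCREASED, DECREASED, UNCHANGED}.

## Dataset model and harmonization

`read_sdf` is a literal reader: molblocks verbatim, property order
preserved, `$$$$`-terminated records, errors carrying the record index. The
compound identifier defaults to the molblock title line and can be switched
to any data field. `build_dataset` mints feature and value IRIs
deterministically under the dataset IRI; values stay raw strings unless a
caller opts into normalization per feature. Feature annotation
(`owl:sameAs` or `rdf:type` into a vocabulary) is manual and idempotent,
mirroring expert curation. The harmonization map is total over each
feature's declared vocabulary; mapping `unspecified` and the numeric
equivocal code to one EQUIVOCAL label is this package's documented choice,
editable in the map file. `query_merged` requires each dataset to register
its call feature and returns identifiers in dataset-then-record order, so
merged queries are deterministic.

## Synthetic inputs and what they show

The seeded generators produce nested schemas (default ~20–40 elements,
depth ≤ 5, ~20 % deliberate cross-context name reuse, ~15 % enumerated
leaves), SDF files in both call dialects with per-record bookkeeping, and
ontology models of known composition. These match the scale of curated
toxicity schemas and datasets this toolchain targets. They do not emulate
real-world messiness — schema imports, malformed molblocks, encoding
problems, free-text fields with embedded delimiters — so passing tests
demonstrate correctness of the lifting, serialization and harmonization
logic, not robustness against arbitrary dirty archives. Property suites run
at desk scale (200 seeded schemas for report totality, 10⁴ draws for the
ratio round-trip), which completes in seconds while exercising the
combinatorics that matter.

## Known limitations

* No OWL reasoning, SPARQL service or REST deployment; the RDF is meant for
  downstream consumption.
* The XSD subset excludes attributes, substitution groups, `xs:all`,
  imports/includes and mixed content.
* SDF reading targets V2000 data-field conventions; structures are carried,
  not interpreted (no standardization or descriptor computation).
* RDF round-trips of datasets recover compounds, features, values and
  annotations, but not molblocks (structure text is not serialized into the
  dataset graph).
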