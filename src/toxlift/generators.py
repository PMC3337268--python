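"""Seeded generators for toy inputs: schemas, SDF files, ontology models.

Each generator returns both the artifact and independent bookkeeping
(element counts, planted duplicate names, per-record field values, model
composition) so tests can check the parsers and converters against a tally
that never went through them. Sizes default to desk scale — a few dozen
elements or records — which is the regime the toolchain targets: curated
toxicity schemas and datasets, not genome-size inputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

from .owl_model import OntologyModel

_NAME_STEMS = (
    "Study", "Background", "Test", "Result", "Compound", "Dose", "Group",
    "Animal", "Organ", "Finding", "Measure", "Exposure", "Duration", "Route",
    "Strain", "Species", "Vehicle", "Control", "Observation", "Tissue",
)


@dataclass
class SchemaBookkeeping:
    n_elements: int
    paths: list[tuple[str, ...]] = dc_field(default_factory=list)
    duplicate_names: dict[str, int] = dc_field(default_factory=dict)


def random_schema(seed: int, n_elements: int = 20, max_children: int = 4,
                  enum_fraction: float = 0.15,
                  duplicate_fraction: float = 0.2) -> tuple[str, SchemaBookkeeping]:
    """Emit a random nested XSD-subset schema of exactly ``n_elements``.

    Names may repeat across contexts (``duplicate_fraction`` of draws reuse
    an already-used stem) to exercise ambiguity detection; sibling names are
    always distinct so paths stay unique.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    rng = random.Random(seed)
    used_names: list[str] = []
    counter = [0]

    def fresh_name(siblings: set[str]) -> str:
        if used_names and rng.random() < duplicate_fraction:
            candidates = [n for n in used_names if n not in siblings]
            if candidates:
                return rng.choice(candidates)
        while True:
            counter[0] += 1
            name = rng.choice(_NAME_STEMS) + str(counter[0])
            if name not in siblings:
                return name

    # grow the tree first so the element count is exact
    root = ("Root",)
    children: dict[tuple[str, ...], list[tuple[str, ...]]] = {root: []}
    for _ in range(n_elements - 1):
        eligible = [p for p in sorted(children)
                    if len(p) < 5 and len(children[p]) < max_children]
        parent = rng.choice(eligible or sorted(children))
        name = fresh_name({c[-1] for c in children[parent]})
        used_names.append(name)
        path = parent + (name,)
        children[parent].append(path)
        children[path] = []

    book = SchemaBookkeeping(n_elements=n_elements, paths=sorted(children))
    lines = ['<?xml version="1.0"?>',
             '<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">']

    def emit(path: tuple[str, ...], indent: str):
        name = path[-1]
        kids = children[path]
        if kids:
            lines.append(f'{indent}<xs:element name="{name}">')
            lines.append(f'{indent}  <xs:complexType><xs:sequence>')
            for kid in kids:
                emit(kid, indent + "    ")
            lines.append(f'{indent}  </xs:sequence></xs:complexType>')
            lines.append(f'{indent}</xs:element>')
        elif rng.random() < enum_fraction:
            lines.append(f'{indent}<xs:element name="{name}">')
            lines.append(f'{indent}  <xs:simpleType><xs:restriction base="xs:string">')
            for v in ("A", "B"):
                lines.append(f'{indent}    <xs:enumeration value="{v}"/>')
            lines.append(f'{indent}  </xs:restriction></xs:simpleType>')
            lines.append(f'{indent}</xs:element>')
        else:
            kind = rng.choice(("xs:string", "xs:integer", "xs:decimal"))
            lines.append(f'{indent}<xs:element name="{name}" type="{kind}"/>')

    emit(root, "  ")
    lines.append("</xs:schema>")

    names: dict[str, int] = {}
    for path in book.paths:
        names[path[-1]] = names.get(path[-1], 0) + 1
    book.duplicate_names = {n: c for n, c in names.items() if c > 1}
    return "\n".join(lines) + "\n", book


_MOLBLOCK = """{title}
  toxlift

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


@dataclass
class SdfBookkeeping:
    n_records: int
    values: dict[str, dict[str, str]] = dc_field(default_factory=dict)  # id -> fields


def random_sdf(seed: int, n_records: int = 10,
               dialect: str = "cpdbas") -> tuple[str, SdfBookkeeping]:
    """Emit a toy SDF in one of the two call-encoding dialects.

    ``cpdbas`` writes an ``ActivityOutcome`` field drawn from
    {active, unspecified, inactive}; ``isscan`` writes a numeric ``Canc``
    field drawn from {1, 2, 3}. A shared ``CASRN``-style id field is always
    present.
    """
    rng = random.Random(seed)
    if dialect == "cpdbas":
        call_field, values = "ActivityOutcome", ("active", "unspecified", "inactive")
    elif dialect == "isscan":
        call_field, values = "Canc", ("1", "2", "3")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    book = SdfBookkeeping(n_records=n_records)
    out = []
    for i in range(n_records):
        ident = f"{dialect.upper()}-{i + 1:04d}"
        call = rng.choice(values)
        mw = f"{rng.uniform(60, 500):.2f}"
        out.append(_MOLBLOCK.format(title=ident))
        out.append(f"> <CASRN>\n{ident}\n\n")
        out.append(f"> <{call_field}>\n{call}\n\n")
        out.append(f"> <MolecularWeight>\n{mw}\n\n")
        out.append("$$$$\n")
        book.values[ident] = {"CASRN": ident, call_field: call,
                              "MolecularWeight": mw}
    return "".join(out), book


@dataclass
class OntologyBookkeeping:
    n_classes: int
    n_object_properties: int
    n_datatype_properties: int
    n_subclass_axioms: int


def random_ontology(seed: int, n_classes: int = 12, n_object_properties: int = 8,
                    n_datatype_properties: int = 5, n_subclass_axioms: int = 4
                    ) -> tuple[OntologyModel, OntologyBookkeeping]:
    """Build a random valid OntologyModel of known composition.

    Subclass axioms always point from a higher class index to a lower one,
    so the subclass relation is acyclic by construction.
    """
    rng = random.Random(seed)
    m = OntologyModel(base_iri="http://example.org/toxlift/random")
    labels = [f"Class{i}" for i in range(n_classes)]
    for label in labels:
        m.add_class(label, rng.choice((None, f"random class {label}")))
    for i in range(n_object_properties):
        dom = tuple(sorted(rng.sample(labels, rng.randint(1, min(3, n_classes)))))
        rng_ = tuple(sorted(rng.sample(labels, rng.randint(1, 2))))
        m.add_object_property(f"hasRel{i}", dom, rng_)
    for i in range(n_datatype_properties):
        dom = tuple(sorted(rng.sample(labels, 1)))
        m.add_datatype_property(f"hasVal{i}", dom,
                                rng.choice(("string", "integer", "decimal")))
    pairs = set()
    while len(pairs) < min(n_subclass_axioms, n_classes * (n_classes - 1) // 2):
        child_i = rng.randrange(1, n_classes)
        parent_i = rng.randrange(0, child_i)
        pairs.add((labels[child_i], labels[parent_i]))
    for child, parent in pairs:
        m.add_subclass(child, parent)
    book = OntologyBookkeeping(
        n_classes=len(m.classes),
        n_object_properties=len(m.object_properties),
        n_datatype_properties=len(m.datatype_properties),
        n_subclass_axioms=len(m.subclass_axioms),
    )
    return m, book
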