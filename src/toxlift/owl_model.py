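"""In-memory OWL ontology model with canonical, byte-stable serialization.

The model is deliberately small: named classes, object/datatype properties
with (possibly union) domains and ranges, explicit subclass axioms, and
human-readable comments. That is exactly the OWL-DL fragment the schema
conversion produces — no restrictions, no individuals, no blank-node
anonymous classes. Union domains/ranges are expressed with ``owl:unionOf``
over *named* helper nodes (including the RDF list cells), so every node in
the emitted graph is an IRI and graph comparison is plain set equality.

Structural consistency (dangling references, subclass cycles, label clashes)
replaces DL reasoning here; the produced ontologies contain no constructs
that would require a tableau reasoner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, XSD, URIRef

from .errors import InvalidModelError

DEFAULT_BASE_IRI = "http://example.org/toxlift/toxml"

_XSD_TYPES = {"string": XSD.string, "integer": XSD.integer, "decimal": XSD.decimal}
_XSD_BACK = {str(v): k for k, v in _XSD_TYPES.items()}


@dataclass(frozen=True)
class ObjectPropertyRecord:
    label: str
    domain: tuple[str, ...]  # sorted class labels; >1 means union
    range: tuple[str, ...]


@dataclass(frozen=True)
class DatatypePropertyRecord:
    label: str
    domain: tuple[str, ...]
    literal_type: str  # string | integer | decimal


@dataclass
class OntologyModel:
    base_iri: str = DEFAULT_BASE_IRI
    classes: dict[str, str | None] = dc_field(default_factory=dict)  # label -> comment
    object_properties: dict[str, ObjectPropertyRecord] = dc_field(default_factory=dict)
    datatype_properties: dict[str, DatatypePropertyRecord] = dc_field(default_factory=dict)
    subclass_axioms: set[tuple[str, str]] = dc_field(default_factory=set)  # (child, parent)

    # -- construction helpers -------------------------------------------------
    def add_class(self, label: str, comment: str | None = None):
        if label not in self.classes or comment is not None:
            self.classes[label] = self.classes.get(label) or comment

    def add_object_property(self, label: str, domain, range_):
        prev = self.object_properties.get(label)
        dom, rng = set(domain), set(range_)
        if prev:
            dom |= set(prev.domain)
            rng |= set(prev.range)
        self.object_properties[label] = ObjectPropertyRecord(
            label, tuple(sorted(dom)), tuple(sorted(rng)))

    def add_datatype_property(self, label: str, domain, literal_type: str = "string"):
        prev = self.datatype_properties.get(label)
        dom = set(domain) | (set(prev.domain) if prev else set())
        self.datatype_properties[label] = DatatypePropertyRecord(
            label, tuple(sorted(dom)), literal_type)

    def add_subclass(self, child: str, parent: str):
        self.subclass_axioms.add((child, parent))

    def iri(self, label: str) -> URIRef:
        return URIRef(f"{self.base_iri}#{label}")

    def __eq__(self, other):
        if not isinstance(other, OntologyModel):
            return NotImplemented
        return (self.base_iri == other.base_iri
                and self.classes == other.classes
                and self.object_properties == other.object_properties
                and self.datatype_properties == other.datatype_properties
                and self.subclass_axioms == other.subclass_axioms)


@dataclass
class OntologyStats:
    n_classes: int
    n_object_properties: int
    n_datatype_properties: int
    n_subclass_axioms: int
    subclass_counts: dict[str, int]


def ontology_stats(model: OntologyModel) -> OntologyStats:
    """Exact cardinalities; ``subclass_counts`` counts *direct* children only."""
    counts: dict[str, int] = {}
    for _child, parent in model.subclass_axioms:
        counts[parent] = counts.get(parent, 0) + 1
    return OntologyStats(
        n_classes=len(model.classes),
        n_object_properties=len(model.object_properties),
        n_datatype_properties=len(model.datatype_properties),
        n_subclass_axioms=len(model.subclass_axioms),
        subclass_counts=dict(sorted(counts.items())),
    )


_LABEL_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def check_structure(model: OntologyModel) -> list[str]:
    """Return all structural issues; empty list iff the model is sound.

    Checks: well-formed labels, domain/range/subclass references resolve to
    declared classes, no class/property label overlap, and subclass acyclicity.
    """
    issues: list[str] = []
    declared = set(model.classes)

    for label in list(model.classes) + list(model.object_properties) + \
            list(model.datatype_properties):
        if not _LABEL_RE.match(label):
            issues.append(f"malformed label {label!r}")

    prop_labels = set(model.object_properties) | set(model.datatype_properties)
    for label in sorted(declared & prop_labels):
        issues.append(f"label {label!r} used for both a class and a property")
    for label in sorted(set(model.object_properties) & set(model.datatype_properties)):
        issues.append(f"label {label!r} declared as both object and datatype property")

    for prop in model.object_properties.values():
        for cls in prop.domain:
            if cls not in declared:
                issues.append(f"object property {prop.label!r}: dangling domain {cls!r}")
        for cls in prop.range:
            if cls not in declared:
                issues.append(f"object property {prop.label!r}: dangling range {cls!r}")
        if not prop.range:
            issues.append(f"object property {prop.label!r}: empty range")
    for prop in model.datatype_properties.values():
        for cls in prop.domain:
            if cls not in declared:
                issues.append(f"datatype property {prop.label!r}: dangling domain {cls!r}")
        if prop.literal_type not in _XSD_TYPES:
            issues.append(f"datatype property {prop.label!r}: "
                          f"unknown literal type {prop.literal_type!r}")

    children: dict[str, list[str]] = {}
    for child, parent in sorted(model.subclass_axioms):
        for end in (child, parent):
            if end not in declared:
                issues.append(f"subclass axiom ({child!r}, {parent!r}): "
                              f"undeclared class {end!r}")
        children.setdefault(parent, []).append(child)

    cycle = _find_cycle({c: [p for ch, p in model.subclass_axioms if ch == c]
                         for c, _ in model.subclass_axioms})
    if cycle:
        issues.append("subclass cycle: " + " < ".join(cycle))
    return issues


def _find_cycle(adj: dict[str, list[str]]) -> list[str] | None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in adj}
    stack: list[str] = []

    def dfs(n: str) -> list[str] | None:
        color[n] = GRAY
        stack.append(n)
        for m in adj.get(n, []):
            if color.get(m, WHITE) == GRAY:
                return stack[stack.index(m):] + [m]
            if color.get(m, WHITE) == WHITE and m in adj:
                found = dfs(m)
                if found:
                    return found
        stack.pop()
        color[n] = BLACK
        return None

    for n in sorted(adj):
        if color[n] == WHITE:
            found = dfs(n)
            if found:
                return found
    return None


# -- RDF graph construction ---------------------------------------------------

def to_graph(model: OntologyModel) -> Graph:
    """Build the model's canonical RDF graph (all nodes named, no bnodes)."""
    g = Graph()
    base = Namespace(model.base_iri + "#")
    g.bind("", base)
    g.bind("owl", OWL)
    g.bind("rdf", RDF)
    g.bind("rdfs", RDFS)
    g.bind("xsd", XSD)

    g.add((URIRef(model.base_iri), RDF.type, OWL.Ontology))

    def class_or_union(labels: tuple[str, ...]) -> URIRef:
        if len(labels) == 1:
            return base[labels[0]]
        union = base["UnionOf_" + "_".join(labels)]
        g.add((union, RDF.type, OWL.Class))
        cell = base["UnionOf_" + "_".join(labels) + "_l0"]
        g.add((union, OWL.unionOf, cell))
        for i, label in enumerate(labels):
            g.add((cell, RDF.first, base[label]))
            nxt = (base["UnionOf_" + "_".join(labels) + f"_l{i + 1}"]
                   if i + 1 < len(labels) else RDF.nil)
            g.add((cell, RDF.rest, nxt))
            cell = nxt
        return union

    for label, comment in model.classes.items():
        g.add((base[label], RDF.type, OWL.Class))
        g.add((base[label], RDFS.label, Literal(label)))
        if comment:
            g.add((base[label], RDFS.comment, Literal(comment)))
    for prop in model.object_properties.values():
        node = base[prop.label]
        g.add((node, RDF.type, OWL.ObjectProperty))
        if prop.domain:
            g.add((node, RDFS.domain, class_or_union(prop.domain)))
        if prop.range:
            g.add((node, RDFS.range, class_or_union(prop.range)))
    for prop in model.datatype_properties.values():
        node = base[prop.label]
        g.add((node, RDF.type, OWL.DatatypeProperty))
        if prop.domain:
            g.add((node, RDFS.domain, class_or_union(prop.domain)))
        g.add((node, RDFS.range, _XSD_TYPES[prop.literal_type]))
    for child, parent in sorted(model.subclass_axioms):
        g.add((base[child], RDFS.subClassOf, base[parent]))
    return g


def canonical_turtle(g: Graph) -> str:
    """Serialize to Turtle with a stable total order of triples.

    One triple per line, prefixed names via rdflib's own term writer (so
    escaping is correct), lines sorted lexicographically. Identical graphs
    give identical bytes on any platform. The output is also valid N3.
    """
    nm = g.namespace_manager
    prefixes = sorted((p, str(ns)) for p, ns in g.namespaces()
                      if p in ("", "owl", "rdf", "rdfs", "xsd", "ot", "dc"))
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in prefixes]
    lines.append("")
    lines.extend(sorted(f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} ." for s, p, o in g))
    return "\n".join(lines) + "\n"


def emit_owl(model: OntologyModel, format: str = "turtle") -> str:
    """Serialize the model; refuses structurally invalid input.

    ``turtle`` uses the canonical sorted-triple writer; ``rdf-xml`` uses the
    standard RDF/XML serializer fed triples in canonical order.
    """
    issues = check_structure(model)
    if issues:
        raise InvalidModelError(issues)
    g = to_graph(model)
    if format in ("turtle", "ttl", "n3"):
        return canonical_turtle(g)
    if format in ("rdf-xml", "xml", "owl"):
        ordered = Graph()
        for prefix, ns in g.namespaces():
            ordered.bind(prefix, ns)
        for triple in sorted(g):
            ordered.add(triple)
        return ordered.serialize(format="xml")
    raise ValueError(f"unknown format {format!r}")


def from_graph(g: Graph) -> OntologyModel:
    """Rebuild an :class:`OntologyModel` from an RDF graph (inverse of emit)."""
    base_iri = None
    for s in g.subjects(RDF.type, OWL.Ontology):
        base_iri = str(s)
    if base_iri is None:
        raise InvalidModelError(["no owl:Ontology header found"])
    model = OntologyModel(base_iri=base_iri)
    prefix = base_iri + "#"

    def label_of(node) -> str:
        return str(node)[len(prefix):]

    union_nodes = set(g.subjects(OWL.unionOf, None))

    def expand(node) -> tuple[str, ...]:
        if node in union_nodes:
            members = []
            cell = next(g.objects(node, OWL.unionOf))
            while cell != RDF.nil:
                members.append(label_of(next(g.objects(cell, RDF.first))))
                cell = next(g.objects(cell, RDF.rest))
            return tuple(sorted(members))
        return (label_of(node),)

    for s in sorted(g.subjects(RDF.type, OWL.Class)):
        if s in union_nodes:
            continue
        comment = g.value(s, RDFS.comment)
        model.add_class(label_of(s), str(comment) if comment else None)
    for s in sorted(g.subjects(RDF.type, OWL.ObjectProperty)):
        dom = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        model.add_object_property(label_of(s),
                                  expand(dom) if dom is not None else (),
                                  expand(rng) if rng is not None else ())
    for s in sorted(g.subjects(RDF.type, OWL.DatatypeProperty)):
        dom = g.value(s, RDFS.domain)
        rng = g.value(s, RDFS.range)
        model.add_datatype_property(label_of(s),
                                    expand(dom) if dom is not None else (),
                                    _XSD_BACK.get(str(rng), "string"))
    for s, o in sorted(g.subject_objects(RDFS.subClassOf)):
        model.add_subclass(label_of(s), label_of(o))
    return model


def parse_owl(text: str, format: str = "turtle") -> OntologyModel:
    g = Graph()
    g.parse(data=text, format="xml" if format in ("rdf-xml", "xml", "owl") else "turtle")
    return from_graph(g)
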