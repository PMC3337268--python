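"""Rule-driven lifting of a schema graph into a flat OWL ontology.

The conversion follows a small set of declarative directives agreed for
ToxML-style schemas:

* every complex (nested) field becomes an OWL class;
* every nesting tuple (F1, F2) becomes an object property ``has<F2>`` with
  domain F1's class and range F2's class — a union of classes when F2 occurs
  under several parents;
* string/numeric leaves become datatype properties ``has<Name>``;
* enumerated or expert-listed leaves are *promoted* to classes so their
  values become named concepts rather than free text;
* container wrappers (``Tests``, ``Compounds`` ...) that only frame repeated
  children are elided, their children re-attached to the container's parent;
* fields sharing a name across contexts are renamed or unified explicitly;
* subclass (IS-A) axioms are emitted only where asserted — the output is
  deliberately flat, because XML nesting does not encode specialization.

The :class:`ConversionReport` accounts for every field in the input graph,
so nothing is dropped silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

import yaml

from .errors import DanglingReferenceError, LabelCollisionError, RuleConflictError
from .owl_model import DEFAULT_BASE_IRI, OntologyModel
from .schema_model import SchemaField, SchemaGraph

#: container names elided by default; wrappers that frame repeated children
DEFAULT_CONTAINERS = ("Tests", "Compounds")

Path = tuple[str, ...]


@dataclass
class RuleSet:
    """Declarative conversion directives.

    ``containers`` entries are either bare names (matched anywhere) or full
    paths; ``renames`` maps a path to a new class label; ``promotions`` lists
    paths of leaves to lift into classes; ``label_unifications`` maps raw
    labels onto a canonical label (sanctioned merges).
    """

    containers: tuple[str | Path, ...] = DEFAULT_CONTAINERS
    renames: dict[Path, str] = dc_field(default_factory=dict)
    promotions: tuple[Path, ...] = ()
    subclass_assertions: tuple[tuple[str, str], ...] = ()
    label_unifications: dict[str, str] = dc_field(default_factory=dict)
    base_iri: str = DEFAULT_BASE_IRI
    container_heuristic: bool = False  # off by default: explicit rules win


@dataclass
class ConversionReport:
    """Per-field disposition plus applied renames and warnings.

    Dispositions partition the field set: ``class`` (first field carrying a
    class label), ``object_property_range`` (further occurrences merged into
    that class), ``datatype_property``, ``promoted_class``,
    ``elided_container``.
    """

    dispositions: dict[Path, str] = dc_field(default_factory=dict)
    renames_applied: dict[Path, str] = dc_field(default_factory=dict)
    warnings: list[str] = dc_field(default_factory=list)


def _parse_path(text: str) -> Path:
    return tuple(part for part in text.strip().strip("/").split("/") if part)


def load_ruleset(text: str) -> RuleSet:
    """Load a RuleSet from its YAML config dialect.

    Keys: ``containers`` (list of names or /-joined paths), ``renames``
    (path -> label), ``promotions`` (list of paths), ``subclasses`` (list of
    ``[child, parent]`` pairs), ``unify`` (label -> label), ``base_iri``.
    """
    raw = yaml.safe_load(text) or {}
    containers = tuple(
        _parse_path(c) if "/" in c else c for c in raw.get("containers", list(DEFAULT_CONTAINERS)))
    return RuleSet(
        containers=containers,
        renames={_parse_path(k): v for k, v in (raw.get("renames") or {}).items()},
        promotions=tuple(_parse_path(p) for p in raw.get("promotions", [])),
        subclass_assertions=tuple((c, p) for c, p in raw.get("subclasses", [])),
        label_unifications=dict(raw.get("unify") or {}),
        base_iri=raw.get("base_iri", DEFAULT_BASE_IRI),
        container_heuristic=bool(raw.get("container_heuristic", False)),
    )


_CAMEL_SPLIT = re.compile(r"[^A-Za-z0-9]+")


def upper_camel(name: str) -> str:
    """Normalize a field name to an UpperCamelCase label (inner caps kept)."""
    parts = [p for p in _CAMEL_SPLIT.split(name) if p]
    return "".join(p[0].upper() + p[1:] for p in parts)


def derive_object_property_name(parent_label: str, child_label: str) -> str:
    """Property naming rule: the relation from parent to child is has<Child>."""
    if not parent_label or not child_label:
        raise ValueError("labels must be non-empty")
    return "has" + upper_camel(child_label)


# -- internal analysis --------------------------------------------------------

class _Analysis:
    """Shared walk: containers elided, labels resolved, edges collected."""

    def __init__(self, graph: SchemaGraph, rules: RuleSet):
        self.graph = graph
        self.rules = rules
        self.report = ConversionReport()
        self._check_rule_paths()
        self.promoted = set(rules.promotions)
        # effective edges: (parent field or None, field) after container elision
        self.edges: list[tuple[SchemaField | None, SchemaField]] = []
        self.containers: list[SchemaField] = []
        self._walk(graph.root, None)
        self.labels: dict[Path, str] = {}
        self.raw_labels: dict[Path, str] = {}
        for _parent, f in self.edges:
            self._label(f)
        # label coherence: a name that denotes a class anywhere denotes it
        # everywhere, so leaf occurrences of a class label are promoted too
        self.class_labels = {self.labels[f.path] for _p, f in self.edges
                             if self._is_class_like(f)}
        self._check_collisions()

    def is_class_like(self, f: SchemaField) -> bool:
        return self._is_class_like(f) or self.labels[f.path] in self.class_labels

    def _check_rule_paths(self):
        index = self.graph.field_index
        for path in list(self.rules.renames) + list(self.rules.promotions):
            if path not in index:
                raise DanglingReferenceError(
                    f"rule references unknown path /{'/'.join(path)}")
        for c in self.rules.containers:
            if isinstance(c, tuple) and c not in index:
                raise DanglingReferenceError(
                    f"container rule references unknown path /{'/'.join(c)}")
        for path in self.rules.promotions:
            if self.graph.field_index[path].value_kind == "complex":
                raise RuleConflictError(
                    f"promotion targets complex field /{'/'.join(path)}")

    def _is_container(self, f: SchemaField) -> bool:
        if f.value_kind != "complex":
            return False
        for c in self.rules.containers:
            if (isinstance(c, tuple) and c == f.path) or c == f.name:
                return True
        if self.rules.container_heuristic and len(f.children) == 1:
            child = f.children[0]
            if (child.value_kind == "complex" and child.max_occurs != 1
                    and f.name.rstrip("s").lower() == child.name.rstrip("s").lower()
                    and f.name != child.name):
                return True
        return False

    def _walk(self, f: SchemaField, effective_parent: SchemaField | None):
        for child in f.children:
            if self._is_container(child):
                self.containers.append(child)
                self._walk(child, effective_parent)
            else:
                self.edges.append((effective_parent, child))
                next_parent = child if self._is_class_like(child) else effective_parent
                self._walk(child, next_parent)

    def _is_class_like(self, f: SchemaField) -> bool:
        if f.value_kind == "complex":
            return True
        return f.path in self.promoted or (
            f.enumeration is not None and f.value_kind == "string")

    def _label(self, f: SchemaField) -> str:
        if f.path in self.labels:
            return self.labels[f.path]
        renamed = self.rules.renames.get(f.path)
        raw = renamed if renamed is not None else upper_camel(f.name)
        final = self.rules.label_unifications.get(raw, raw)
        if renamed is not None or final != upper_camel(f.name):
            self.report.renames_applied[f.path] = final
        self.labels[f.path] = final
        self.raw_labels[f.path] = raw
        return final

    def _check_collisions(self):
        by_label: dict[str, list[Path]] = {}
        for _parent, f in self.edges:
            if self.is_class_like(f):
                by_label.setdefault(self.labels[f.path], []).append(f.path)
        for label, paths in sorted(by_label.items()):
            names = {upper_camel(p[-1]) for p in paths}
            if len(names) < 2:
                continue  # natural reuse of one name: merges by design
            for path in paths:
                changed = self.labels[path] != upper_camel(path[-1])
                via_unification = (
                    self.rules.label_unifications.get(self.raw_labels[path]) == label
                    and self.raw_labels[path] != label)
                if changed and not via_unification:
                    raise LabelCollisionError(label, paths)


def classify_fields(graph: SchemaGraph, rules: RuleSet) -> ConversionReport:
    """Assign every field a disposition without building the ontology."""
    ana = _Analysis(graph, rules)
    report = ana.report
    seen_class_labels: set[str] = set()
    order = {f.path: i for i, (_p, f) in enumerate(ana.edges)}
    for path in sorted(graph.field_index, key=lambda p: order.get(p, -1)):
        f = graph.field_index[path]
        if f in ana.containers:
            report.dispositions[path] = "elided_container"
        elif f.value_kind != "complex" and ana._is_class_like(f):
            report.dispositions[path] = "promoted_class"
            seen_class_labels.add(ana.labels[path])
        elif ana.is_class_like(f):
            label = ana.labels[path]
            if label in seen_class_labels:
                report.dispositions[path] = "object_property_range"
            else:
                report.dispositions[path] = "class"
                seen_class_labels.add(label)
        else:
            report.dispositions[path] = "datatype_property"
    report.dispositions = dict(sorted(report.dispositions.items()))
    return report


def convert(graph: SchemaGraph, rules: RuleSet | None = None
            ) -> tuple[OntologyModel, ConversionReport]:
    """Apply the conversion rules; returns the ontology and a full accounting.

    See the module docstring for the rule semantics. Deterministic: identical
    (graph, rules) inputs give identical models.
    """
    rules = rules or RuleSet()
    ana = _Analysis(graph, rules)
    report = classify_fields(graph, rules)
    report.renames_applied = ana.report.renames_applied
    model = OntologyModel(base_iri=rules.base_iri)

    # classes, deduplicated by final label
    label_paths: dict[str, list[Path]] = {}
    for _parent, f in ana.edges:
        if ana.is_class_like(f):
            label_paths.setdefault(ana.labels[f.path], []).append(f.path)
    for label, paths in sorted(label_paths.items()):
        comment = None
        enum_values: list[str] = []
        for p in paths:
            fld = graph.field_index[p]
            if fld.enumeration:
                enum_values.extend(v for v in fld.enumeration if v not in enum_values)
        if enum_values:
            comment = "Allowed values: " + ", ".join(enum_values)
        model.add_class(label, comment)
        if len(paths) > 1:
            report.warnings.append(
                f"label {label!r} merges {len(paths)} occurrences: "
                + "; ".join("/".join(p) for p in paths))

    # properties from surviving nesting tuples
    for parent, f in ana.edges:
        if parent is None:
            continue  # top-level classes have no incoming relation
        parent_label = ana.labels[parent.path]
        if ana.is_class_like(f):
            prop = derive_object_property_name(parent_label, ana.labels[f.path])
            model.add_object_property(prop, (parent_label,), (ana.labels[f.path],))
        else:
            prop = "has" + ana.labels[f.path]
            literal = f.value_kind if f.value_kind in ("string", "integer", "decimal") \
                else "string"
            prev = model.datatype_properties.get(prop)
            if prev and prev.literal_type != literal:
                report.warnings.append(
                    f"datatype property {prop!r} mixes literal types "
                    f"({prev.literal_type} vs {literal}); widened to string")
                literal = "string"
            model.add_datatype_property(prop, (parent_label,), literal)

    for child, parent in rules.subclass_assertions:
        for end in (child, parent):
            if end not in model.classes:
                raise DanglingReferenceError(
                    f"subclass assertion ({child}, {parent}): no class {end!r}")
        model.add_subclass(child, parent)

    for name in sorted({c for c in rules.containers if isinstance(c, str)}):
        if not any(f.name == name for f in ana.containers):
            report.warnings.append(f"container rule {name!r} matched no field")
    return model, report
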