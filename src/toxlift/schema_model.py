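"""Parse an XSD-subset schema into a language-neutral field graph.

The supported subset covers what nested data-exchange schemas in the ToxML
style actually use: ``xs:element`` (inline or via named global ``complexType``
/ ``simpleType``), ``xs:sequence`` and ``xs:choice`` (both read as plain
nesting — ordering carries no ontological meaning here), ``xs:simpleType``
restrictions with ``xs:enumeration`` facets, and ``minOccurs``/``maxOccurs``.
Anything else (``xs:any``, ``xs:attribute``, imports, ...) is a hard
:class:`~toxlift.errors.UnsupportedConstructError` — the downstream
conversion must account for every field, so silent skipping is not allowed.

Named global types are expanded at each point of use; the graph therefore has
one :class:`SchemaField` per *use* of an element declaration, keyed by its
full path from the document root.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from lxml import etree

from .errors import SchemaParseError, UnsupportedConstructError

XS = "http://www.w3.org/2001/XMLSchema"

#: leaf value kinds recognised from XSD built-in types
_BUILTIN_KINDS = {
    "string": "string",
    "token": "string",
    "normalizedString": "string",
    "integer": "integer",
    "int": "integer",
    "long": "integer",
    "nonNegativeInteger": "integer",
    "positiveInteger": "integer",
    "decimal": "decimal",
    "double": "decimal",
    "float": "decimal",
}

_SUPPORTED_TAGS = {
    f"{{{XS}}}schema",
    f"{{{XS}}}element",
    f"{{{XS}}}complexType",
    f"{{{XS}}}simpleType",
    f"{{{XS}}}sequence",
    f"{{{XS}}}choice",
    f"{{{XS}}}restriction",
    f"{{{XS}}}enumeration",
    f"{{{XS}}}annotation",
    f"{{{XS}}}documentation",
}


@dataclass
class SchemaField:
    """One declared element at one position in the schema tree.

    ``path`` is the ordered tuple of element names from the document root down
    to (and including) this field; it is the unique key within a graph.
    """

    name: str
    path: tuple[str, ...]
    value_kind: str = "string"  # complex | string | integer | decimal
    children: list["SchemaField"] = dc_field(default_factory=list)
    enumeration: list[str] | None = None
    min_occurs: int = 1
    max_occurs: int | str = 1  # positive int or "unbounded"

    def walk(self):
        """Yield this field and every descendant, pre-order."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class SchemaGraph:
    """Parsed schema: a synthetic document-level root plus a path index.

    The root node (``path == ()``) stands for the schema document itself and
    is not a declared element; ``field_index`` maps each declared element's
    path to its field, so ``len(field_index)`` counts element declarations
    (after expansion of named global types).
    """

    root: SchemaField
    field_index: dict[tuple[str, ...], SchemaField] = dc_field(default_factory=dict)

    def __post_init__(self):
        if not self.field_index:
            for f in self.root.walk():
                if f.path:
                    self.field_index[f.path] = f

    def __eq__(self, other):
        if not isinstance(other, SchemaGraph):
            return NotImplemented
        return _field_key(self.root) == _field_key(other.root)


def _field_key(f: SchemaField):
    return (
        f.name,
        f.path,
        f.value_kind,
        tuple(f.enumeration) if f.enumeration is not None else None,
        f.min_occurs,
        f.max_occurs,
        tuple(_field_key(c) for c in f.children),
    )


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else "?"


def _check_supported(node, path):
    if not isinstance(node.tag, str):  # comments / PIs
        return False
    if node.tag not in _SUPPORTED_TAGS:
        raise UnsupportedConstructError(f"xs:{_local(node.tag)}", path)
    return True


def _parse_occurs(node) -> tuple[int, int | str]:
    min_o = int(node.get("minOccurs", "1"))
    raw_max = node.get("maxOccurs", "1")
    max_o: int | str = "unbounded" if raw_max == "unbounded" else int(raw_max)
    return min_o, max_o


def _strip_prefix(type_name: str) -> str:
    return type_name.split(":", 1)[1] if ":" in type_name else type_name


class _Parser:
    def __init__(self, root_el):
        self.named_complex = {}
        self.named_simple = {}
        for child in root_el:
            if not _check_supported(child, ()):
                continue
            local = _local(child.tag)
            name = child.get("name")
            if local == "complexType" and name:
                self.named_complex[name] = child
            elif local == "simpleType" and name:
                self.named_simple[name] = child

    def element(self, node, parent_path: tuple[str, ...]) -> SchemaField:
        name = node.get("name")
        if name is None:
            raise UnsupportedConstructError("xs:element without name (ref?)", parent_path)
        path = parent_path + (name,)
        min_o, max_o = _parse_occurs(node)
        f = SchemaField(name=name, path=path, min_occurs=min_o, max_occurs=max_o)

        type_ref = node.get("type")
        inline = [c for c in node if _check_supported(c, path)
                  and _local(c.tag) not in ("annotation",)]
        if type_ref is not None:
            self._apply_type_ref(f, _strip_prefix(type_ref), path)
        for sub in inline:
            local = _local(sub.tag)
            if local == "complexType":
                f.children = self._complex_children(sub, path)
            elif local == "simpleType":
                f.value_kind, f.enumeration = self._simple(sub, path)
            else:
                raise UnsupportedConstructError(f"xs:{local}", path)
        f.value_kind = "complex" if f.children else (
            f.value_kind if f.value_kind != "complex" else "string")
        return f

    def _apply_type_ref(self, f: SchemaField, type_name: str, path):
        if type_name in _BUILTIN_KINDS:
            f.value_kind = _BUILTIN_KINDS[type_name]
        elif type_name in self.named_complex:
            f.children = self._complex_children(self.named_complex[type_name], path)
            f.value_kind = "complex"
        elif type_name in self.named_simple:
            f.value_kind, f.enumeration = self._simple(self.named_simple[type_name], path)
        else:
            raise UnsupportedConstructError(f"type {type_name!r}", path)

    def _complex_children(self, ct_node, path) -> list[SchemaField]:
        children: list[SchemaField] = []
        for sub in ct_node:
            if not _check_supported(sub, path):
                continue
            local = _local(sub.tag)
            if local in ("sequence", "choice"):
                children.extend(self._particle(sub, path))
            elif local == "annotation":
                continue
            else:
                raise UnsupportedConstructError(f"xs:{local}", path)
        return children

    def _particle(self, node, path) -> list[SchemaField]:
        out = []
        for sub in node:
            if not _check_supported(sub, path):
                continue
            local = _local(sub.tag)
            if local == "element":
                out.append(self.element(sub, path))
            elif local in ("sequence", "choice"):
                out.extend(self._particle(sub, path))
            else:
                raise UnsupportedConstructError(f"xs:{local}", path)
        return out

    def _simple(self, st_node, path) -> tuple[str, list[str] | None]:
        for sub in st_node:
            if not _check_supported(sub, path):
                continue
            if _local(sub.tag) == "annotation":
                continue
            if _local(sub.tag) != "restriction":
                raise UnsupportedConstructError(f"xs:{_local(sub.tag)}", path)
            base = _strip_prefix(sub.get("base", "string"))
            kind = _BUILTIN_KINDS.get(base)
            if kind is None:
                raise UnsupportedConstructError(f"restriction base {base!r}", path)
            values = []
            for facet in sub:
                if not _check_supported(facet, path):
                    continue
                if _local(facet.tag) == "annotation":
                    continue
                if _local(facet.tag) != "enumeration":
                    raise UnsupportedConstructError(f"xs:{_local(facet.tag)}", path)
                values.append(facet.get("value", ""))
            if values and kind != "string":
                raise UnsupportedConstructError(
                    f"enumeration on non-string base {base!r}", path)
            return kind, values or None
        return "string", None


def parse_schema(schema_text: str | bytes) -> SchemaGraph:
    """Parse an XSD-subset document into a :class:`SchemaGraph`.

    Raises :class:`SchemaParseError` on malformed XML (naming the line) and
    :class:`UnsupportedConstructError` on anything outside the subset.
    """
    if isinstance(schema_text, str):
        schema_text = schema_text.encode("utf-8")
    try:
        doc = etree.fromstring(schema_text)
    except etree.XMLSyntaxError as exc:
        raise SchemaParseError(str(exc.args[0] if exc.args else exc),
                               line=getattr(exc, "lineno", None)) from exc
    if doc.tag != f"{{{XS}}}schema":
        raise SchemaParseError(f"document root is <{_local(doc.tag)}>, expected xs:schema")

    parser = _Parser(doc)
    root = SchemaField(name="", path=(), value_kind="complex")
    for child in doc:
        if not _check_supported(child, ()):
            continue
        local = _local(child.tag)
        if local == "element":
            root.children.append(parser.element(child, ()))
        elif local in ("complexType", "simpleType", "annotation"):
            continue  # named global types are expanded at use sites
        else:
            raise UnsupportedConstructError(f"xs:{local}", ())
    if not root.children:
        root.value_kind = "string"

    graph = SchemaGraph(root=root)
    # paths are unique by construction unless the schema declares two siblings
    # with the same name; count to be sure
    n_fields = sum(1 for f in root.walk() if f.path)
    if n_fields != len(graph.field_index):
        raise SchemaParseError("duplicate sibling element names produce non-unique paths")
    return graph


def serialize_schema(graph: SchemaGraph) -> str:
    """Emit the graph back as XSD text (inverse of :func:`parse_schema`).

    Only inline anonymous types are emitted; re-parsing yields an equal graph.
    """
    nsmap = {"xs": XS}
    doc = etree.Element(f"{{{XS}}}schema", nsmap=nsmap)

    def emit(field: SchemaField, parent):
        el = etree.SubElement(parent, f"{{{XS}}}element", name=field.name)
        if field.min_occurs != 1:
            el.set("minOccurs", str(field.min_occurs))
        if field.max_occurs != 1:
            el.set("maxOccurs", str(field.max_occurs))
        if field.value_kind == "complex":
            ct = etree.SubElement(el, f"{{{XS}}}complexType")
            seq = etree.SubElement(ct, f"{{{XS}}}sequence")
            for child in field.children:
                emit(child, seq)
        elif field.enumeration is not None:
            st = etree.SubElement(el, f"{{{XS}}}simpleType")
            restr = etree.SubElement(st, f"{{{XS}}}restriction", base="xs:string")
            for v in field.enumeration:
                etree.SubElement(restr, f"{{{XS}}}enumeration", value=v)
        else:
            el.set("type", f"xs:{ {'string': 'string', 'integer': 'integer', 'decimal': 'decimal'}[field.value_kind] }")

    for child in graph.root.children:
        emit(child, doc)
    return etree.tostring(doc, pretty_print=True, encoding="unicode")


def ambiguous_names(graph: SchemaGraph) -> dict[str, list[tuple[str, ...]]]:
    """Names used at two or more distinct paths, each with all its paths.

    These are the candidates for the rename rules: the same label in
    different contexts usually means different things.
    """
    by_name: dict[str, list[tuple[str, ...]]] = {}
    for path in sorted(graph.field_index):
        by_name.setdefault(path[-1], []).append(path)
    return {name: paths for name, paths in sorted(by_name.items()) if len(paths) >= 2}
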