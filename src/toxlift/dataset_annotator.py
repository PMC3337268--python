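"""OpenTox-style RDF representation of SDF chemical datasets.

Public toxicity collections ship as SDF files whose data fields are only
documented in prose: one database records the carcinogenicity call in an
``ActivityOutcome`` field (``active`` / ``unspecified`` / ``inactive``),
another in a numeric ``Canc`` field (3 = carcinogen, 2 = equivocal,
1 = non-carcinogen). This module reads such files, lifts them into a uniform
dataset/feature/value model (the ``ot:`` vocabulary), attaches ontology
annotations to features (``owl:sameAs`` or ``rdf:type`` links into the
endpoint/organ vocabularies), and harmonizes the divergent call encodings
onto one POSITIVE / EQUIVOCAL / NEGATIVE scale so the datasets become
jointly queryable.

The SDF reader is deliberately literal: molblocks are kept verbatim and
property order is preserved, because annotation must not alter the source
record; a structurally broken record is an error carrying its index.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import yaml
from rdflib import Graph, Literal, Namespace, RDF, OWL, URIRef

from .errors import DatasetError, InvalidModelError, SdfParseError, UnmappedValueError
from .owl_model import canonical_turtle

#: minimal OpenTox framework vocabulary; the component classes a dataset
#: representation needs (Algorithm/Model are constants only, never emitted)
OT = Namespace("http://www.opentox.org/api/1.1#")
OT_TERMS = ("Dataset", "DataEntry", "Feature", "FeatureValue", "Compound",
            "Algorithm", "Model")

HARMONIZED_CALLS = ("POSITIVE", "EQUIVOCAL", "NEGATIVE")

LINK_KINDS = ("same_as", "has_type")
_LINK_PREDICATES = {"same_as": OWL.sameAs, "has_type": RDF.type}


@dataclass
class CompoundRecord:
    """One SDF record: identifier, verbatim molblock, ordered data fields."""

    identifier: str
    structure_block: str
    properties: dict[str, str] = dc_field(default_factory=dict)


@dataclass
class FeatureRecord:
    name: str
    iri: str
    annotations: list[tuple[str, str]] = dc_field(default_factory=list)  # (kind, target)


@dataclass
class DatasetModel:
    """Uniform dataset representation: compounds x features -> raw values."""

    dataset_iri: str
    compounds: list[CompoundRecord] = dc_field(default_factory=list)
    features: dict[str, FeatureRecord] = dc_field(default_factory=dict)
    values: list[tuple[str, str, str]] = dc_field(default_factory=list)
    call_feature: str | None = None  # feature carrying the activity call


@dataclass
class HarmonizationMap:
    """(feature name, raw value) -> harmonized call, total per feature."""

    entries: dict[tuple[str, str], str] = dc_field(default_factory=dict)


def default_harmonization_map() -> HarmonizationMap:
    """The bundled cross-database call map.

    ``unspecified`` and the numeric equivocal code are both mapped to
    EQUIVOCAL; that equivalence is a documented mapping choice, editable in
    the map file, not a claim made by either source database.
    """
    return HarmonizationMap(entries={
        ("ActivityOutcome", "active"): "POSITIVE",
        ("ActivityOutcome", "unspecified"): "EQUIVOCAL",
        ("ActivityOutcome", "inactive"): "NEGATIVE",
        ("Canc", "3"): "POSITIVE",
        ("Canc", "2"): "EQUIVOCAL",
        ("Canc", "1"): "NEGATIVE",
    })


def load_harmonization_map(text: str) -> HarmonizationMap:
    """Load a map from YAML: ``{feature: {raw value: CALL}}``."""
    raw = yaml.safe_load(text) or {}
    entries = {}
    for feature, mapping in raw.items():
        for value, call in mapping.items():
            call = str(call).upper()
            if call not in HARMONIZED_CALLS:
                raise DatasetError(f"unknown harmonized call {call!r} "
                                   f"for {feature}={value}")
            entries[(str(feature), str(value))] = call
    return HarmonizationMap(entries=entries)


# -- SDF reading --------------------------------------------------------------

def read_sdf(text: str, id_field: str | None = None) -> list[CompoundRecord]:
    """Split an SDF V2000 document into records.

    The identifier defaults to the molblock title line; ``id_field`` names a
    data field to use instead. Records must be ``$$$$``-terminated; property
    blocks are ``> <name>`` headers followed by value lines.
    """
    records: list[CompoundRecord] = []
    if not text.strip():
        return records
    chunks = text.split("\n$$$$")
    # a well-formed file ends with the delimiter: last chunk is whitespace
    if chunks[-1].strip():
        raise SdfParseError("truncated record: missing $$$$ delimiter", len(chunks) - 1)
    for index, chunk in enumerate(chunks[:-1]):
        chunk = chunk.lstrip("\n")
        lines = chunk.split("\n")
        end_idx = next((i for i, ln in enumerate(lines)
                        if ln.startswith("M  END")), None)
        if end_idx is None:
            raise SdfParseError("molblock has no 'M  END' line", index)
        structure_block = "\n".join(lines[:end_idx + 1]) + "\n"
        properties: dict[str, str] = {}
        i = end_idx + 1
        while i < len(lines):
            line = lines[i]
            if not line.strip():
                i += 1
                continue
            if not line.startswith(">"):
                raise SdfParseError(f"unexpected line in data block: {line!r}", index)
            if "<" not in line or ">" not in line[1:]:
                raise SdfParseError(f"malformed field header: {line!r}", index)
            name = line[line.index("<") + 1:line.rindex(">")]
            if name in properties:
                raise SdfParseError(f"duplicate field {name!r}", index)
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip():
                value_lines.append(lines[i])
                i += 1
            properties[name] = "\n".join(value_lines)
        title = lines[0].strip() if lines else ""
        if id_field is not None:
            identifier = properties.get(id_field, "")
            if not identifier:
                raise SdfParseError(f"missing identifier field {id_field!r}", index)
        else:
            identifier = title
        if not identifier:
            raise SdfParseError("empty identifier (blank title line)", index)
        records.append(CompoundRecord(identifier, structure_block, properties))
    return records


# -- dataset model ------------------------------------------------------------

def build_dataset(records: list[CompoundRecord], dataset_iri: str,
                  call_feature: str | None = None) -> DatasetModel:
    """Lift records into the uniform dataset model.

    One feature per distinct property name (IRIs minted deterministically
    under ``dataset_iri``); every (compound, field, value) becomes a value
    triple. Duplicate compound identifiers are an error.
    """
    seen: set[str] = set()
    dupes: list[str] = []
    for r in records:
        if r.identifier in seen:
            dupes.append(r.identifier)
        seen.add(r.identifier)
    if dupes:
        raise DatasetError(f"duplicate compound identifiers: {sorted(set(dupes))}")
    model = DatasetModel(dataset_iri=dataset_iri.rstrip("/"))
    for record in records:
        model.compounds.append(record)
        for name, value in record.properties.items():
            if name not in model.features:
                model.features[name] = FeatureRecord(
                    name=name, iri=f"{model.dataset_iri}/feature/{name}")
            model.values.append((record.identifier, name, value))
    if call_feature is not None:
        if call_feature not in model.features:
            raise DatasetError(f"call feature {call_feature!r} not in dataset")
        model.call_feature = call_feature
    return model


def annotate_feature(model: DatasetModel, feature_name: str, target_iri: str,
                     link_kind: str = "same_as") -> DatasetModel:
    """Return a copy of the model with an ontology link on one feature.

    Idempotent: re-applying an identical (target, kind) pair is a no-op.
    Mirrors the manual curation step — links are asserted by an expert, never
    guessed from the feature name.
    """
    if link_kind not in LINK_KINDS:
        raise DatasetError(f"unknown link kind {link_kind!r}; expected {LINK_KINDS}")
    if feature_name not in model.features:
        raise DatasetError(f"unknown feature {feature_name!r}")
    out = copy.deepcopy(model)
    annotations = out.features[feature_name].annotations
    if (link_kind, target_iri) not in annotations:
        annotations.append((link_kind, target_iri))
    return out


def harmonize_call(feature_name: str, raw_value: str,
                   harmonization_map: HarmonizationMap | None = None) -> str:
    """Map a database-specific activity value onto the harmonized call scale."""
    harmonization_map = harmonization_map or default_harmonization_map()
    try:
        return harmonization_map.entries[(feature_name, str(raw_value).strip())]
    except KeyError:
        raise UnmappedValueError(feature_name, raw_value) from None


def query_merged(datasets: list[DatasetModel],
                 harmonization_map: HarmonizationMap | None = None,
                 call: str = "POSITIVE") -> list[str]:
    """Identifiers of all compounds whose harmonized call equals ``call``.

    Each dataset must have its call feature registered; results are ordered
    by dataset then compound order, so the merge is deterministic.
    """
    if call not in HARMONIZED_CALLS:
        raise DatasetError(f"unknown call {call!r}; expected one of {HARMONIZED_CALLS}")
    out: list[str] = []
    for ds in datasets:
        if ds.call_feature is None:
            raise DatasetError(f"dataset {ds.dataset_iri} has no registered call feature")
        for compound_id, feature, value in ds.values:
            if feature == ds.call_feature and \
                    harmonize_call(feature, value, harmonization_map) == call:
                out.append(compound_id)
    return out


# -- RDF emission -------------------------------------------------------------

def dataset_to_graph(model: DatasetModel) -> Graph:
    """Build the ot:Dataset RDF graph; all nodes named under the dataset IRI."""
    g = Graph()
    g.bind("ot", OT)
    g.bind("owl", OWL)
    g.bind("rdf", RDF)
    base = model.dataset_iri
    dataset = URIRef(base)
    g.add((dataset, RDF.type, OT.Dataset))
    for feature in model.features.values():
        node = URIRef(feature.iri)
        g.add((node, RDF.type, OT.Feature))
        g.add((node, OT.hasSource, dataset))
        g.add((node, OT.featureName, Literal(feature.name)))
        for kind, target in feature.annotations:
            g.add((node, _LINK_PREDICATES[kind], URIRef(target)))
    for compound in model.compounds:
        comp = URIRef(f"{base}/compound/{compound.identifier}")
        entry = URIRef(f"{base}/dataEntry/{compound.identifier}")
        g.add((comp, RDF.type, OT.Compound))
        g.add((dataset, OT.dataEntry, entry))
        g.add((entry, RDF.type, OT.DataEntry))
        g.add((entry, OT.compound, comp))
    for compound_id, feature, value in model.values:
        entry = URIRef(f"{base}/dataEntry/{compound_id}")
        vnode = URIRef(f"{base}/value/{compound_id}/{feature}")
        g.add((entry, OT.values, vnode))
        g.add((vnode, RDF.type, OT.FeatureValue))
        g.add((vnode, OT.feature, URIRef(model.features[feature].iri)))
        g.add((vnode, OT.value, Literal(value)))
    return g


def emit_dataset_rdf(model: DatasetModel, format: str = "turtle") -> str:
    """Canonical Turtle/N3 serialization of the dataset model."""
    _validate_dataset(model)
    if format not in ("turtle", "ttl", "n3"):
        raise ValueError(f"unknown format {format!r}")
    return canonical_turtle(dataset_to_graph(model))


def _validate_dataset(model: DatasetModel):
    issues = []
    ids = {c.identifier for c in model.compounds}
    for compound_id, feature, _value in model.values:
        if compound_id not in ids:
            issues.append(f"value references undeclared compound {compound_id!r}")
        if feature not in model.features:
            issues.append(f"value references undeclared feature {feature!r}")
    iris = [f.iri for f in model.features.values()]
    if len(set(iris)) != len(iris):
        issues.append("feature IRIs are not unique")
    if issues:
        raise InvalidModelError(issues)


def parse_dataset_rdf(text: str, format: str = "turtle") -> DatasetModel:
    """Rebuild a DatasetModel (sans molblocks) from its RDF serialization.

    Structure blocks are not carried in RDF, so round-tripping recovers
    compounds, features, values and annotations, with empty molblocks.
    """
    g = Graph()
    g.parse(data=text, format="turtle")
    dataset = next(g.subjects(RDF.type, OT.Dataset))
    model = DatasetModel(dataset_iri=str(dataset))
    for node in sorted(g.subjects(RDF.type, OT.Feature)):
        name = str(g.value(node, OT.featureName))
        feature = FeatureRecord(name=name, iri=str(node))
        for kind, predicate in _LINK_PREDICATES.items():
            for target in sorted(g.objects(node, predicate)):
                if target == OT.Feature:  # the node's own ot:Feature typing
                    continue
                feature.annotations.append((kind, str(target)))
        model.features[name] = feature
    iri_to_name = {f.iri: f.name for f in model.features.values()}
    for entry in sorted(g.objects(dataset, OT.dataEntry)):
        comp = g.value(entry, OT.compound)
        identifier = str(comp).rsplit("/", 1)[-1]
        record = CompoundRecord(identifier, structure_block="")
        for vnode in sorted(g.objects(entry, OT.values)):
            fname = iri_to_name[str(g.value(vnode, OT.feature))]
            value = str(g.value(vnode, OT.value))
            record.properties[fname] = value
            model.values.append((identifier, fname, value))
        model.compounds.append(record)
    return model
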