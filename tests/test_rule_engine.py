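"""Conversion rules: classes vs properties, containers, renames, unions."""

import pytest

from toxlift import (RuleSet, classify_fields, convert,
                     derive_object_property_name, load_ruleset, parse_schema,
                     upper_camel)
from toxlift.errors import (DanglingReferenceError, LabelCollisionError,
                            RuleConflictError)
from toxlift.generators import random_schema

FIG_STYLE = """<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="Study"><xs:complexType><xs:sequence>
    <xs:element name="Background"><xs:complexType><xs:sequence>
      <xs:element name="ReferenceCompound"><xs:complexType><xs:sequence>
        <xs:element name="Name" type="xs:string"/>
      </xs:sequence></xs:complexType></xs:element>
    </xs:sequence></xs:complexType></xs:element>
  </xs:sequence></xs:complexType></xs:element>
</xs:schema>"""


@pytest.mark.parametrize("parent,child,expected", [
    ("Study", "Background", "hasBackground"),
    ("Study", "ReferenceCompound", "hasReferenceCompound"),
    ("X", "X", "hasX"),
    ("TreatmentGroup", "treatment results", "hasTreatmentResults"),
])
def test_object_property_naming(parent, child, expected):
    assert derive_object_property_name(parent, child) == expected


def test_nested_tuple_becomes_class_pair_with_object_property():
    model, _ = convert(parse_schema(FIG_STYLE), RuleSet(containers=()))
    assert {"Study", "Background", "ReferenceCompound"} <= set(model.classes)
    assert model.object_properties["hasBackground"].domain == ("Study",)
    assert model.object_properties["hasBackground"].range == ("Background",)
    assert model.object_properties["hasReferenceCompound"].domain == ("Background",)
    assert model.object_properties["hasReferenceCompound"].range == ("ReferenceCompound",)


def test_string_leaf_becomes_datatype_property():
    model, _ = convert(parse_schema(FIG_STYLE), RuleSet(containers=()))
    prop = model.datatype_properties["hasName"]
    assert prop.domain == ("ReferenceCompound",) and prop.literal_type == "string"


def test_enumerated_leaf_promoted_to_class(toxml_mini_graph, default_rules):
    model, report = convert(toxml_mini_graph, default_rules)
    assert "Sex" in model.classes
    assert model.object_properties["hasSex"].domain == ("TestAnimal",)
    assert model.object_properties["hasSex"].range == ("Sex",)
    assert "hasSex" not in model.datatype_properties
    path = ("ToxML", "Study", "Tests", "Test", "TestAnimal", "Sex")
    assert report.dispositions[path] == "promoted_class"


def test_containers_elided_and_children_reattached(converted):
    model, report = converted
    assert "Tests" not in model.classes and "Compounds" not in model.classes
    # Test survives under both Study and ChronicStudies -> union domain
    assert model.object_properties["hasTest"].domain == ("ChronicStudies", "Study")
    assert model.object_properties["hasTest"].range == ("Test",)
    assert report.dispositions[("ToxML", "Study", "Tests")] == "elided_container"


def test_rename_applies_in_context_only(converted):
    model, _ = converted
    assert "TreatmentResults" in model.classes
    assert "Results" in model.classes  # the study-level one keeps its name
    assert model.object_properties["hasTreatmentResults"].domain == ("TreatmentGroup",)
    assert model.object_properties["hasResults"].domain == ("Study",)


def test_subclass_assertions_are_the_only_isa_links(converted):
    model, _ = converted
    assert model.subclass_axioms == {("ChronicStudies", "Study")}


def test_dangling_subclass_assertion_raises(toxml_mini_graph, default_rules):
    bad = RuleSet(containers=default_rules.containers,
                  renames=default_rules.renames,
                  subclass_assertions=(("NoSuchClass", "Study"),))
    with pytest.raises(DanglingReferenceError):
        convert(toxml_mini_graph, bad)


def test_promotion_of_complex_field_is_rule_conflict():
    graph = parse_schema(FIG_STYLE)
    rules = RuleSet(containers=(), promotions=(("Study", "Background"),))
    with pytest.raises(RuleConflictError):
        classify_fields(graph, rules)


def test_rename_collision_without_unification_raises():
    text = """<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
      <xs:element name="Root"><xs:complexType><xs:sequence>
        <xs:element name="A"><xs:complexType><xs:sequence>
          <xs:element name="X" type="xs:string"/>
        </xs:sequence></xs:complexType></xs:element>
        <xs:element name="B"><xs:complexType><xs:sequence>
          <xs:element name="Y" type="xs:string"/>
        </xs:sequence></xs:complexType></xs:element>
      </xs:sequence></xs:complexType></xs:element>
    </xs:schema>"""
    graph = parse_schema(text)
    rules = RuleSet(containers=(), renames={("Root", "A"): "B"})
    with pytest.raises(LabelCollisionError) as err:
        convert(graph, rules)
    assert ("Root", "A") in err.value.paths

    # an explicit unification sanctions the merge
    ok = RuleSet(containers=(), label_unifications={"A": "B"})
    model, _ = convert(graph, ok)
    assert "A" not in model.classes and "B" in model.classes


def test_unification_is_idempotent(toxml_mini_graph, default_rules):
    model1, _ = convert(toxml_mini_graph, default_rules)
    # a unification mapping a label to itself changes nothing
    rules2 = RuleSet(containers=default_rules.containers,
                     renames=default_rules.renames,
                     promotions=default_rules.promotions,
                     subclass_assertions=default_rules.subclass_assertions,
                     label_unifications={"Study": "Study"},
                     base_iri=default_rules.base_iri)
    model2, _ = convert(toxml_mini_graph, rules2)
    assert model1 == model2


def test_rule_referencing_unknown_path_raises(toxml_mini_graph):
    with pytest.raises(DanglingReferenceError):
        convert(toxml_mini_graph, RuleSet(renames={("No", "Such"): "X"}))


def test_single_complex_root_gives_single_class_disposition():
    text = ('<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">'
            '<xs:element name="Root"><xs:complexType><xs:sequence>'
            '<xs:element name="Leaf" type="xs:string"/>'
            '</xs:sequence></xs:complexType></xs:element></xs:schema>')
    report = classify_fields(parse_schema(text), RuleSet(containers=()))
    assert report.dispositions[("Root",)] == "class"
    assert report.dispositions[("Root", "Leaf")] == "datatype_property"


@pytest.mark.parametrize("seed", range(20))
def test_report_totality_on_random_schemas(seed):
    """Every field gets exactly one disposition (fuzzed)."""
    text, _ = random_schema(seed, n_elements=40)
    graph = parse_schema(text)
    report = classify_fields(graph, RuleSet(containers=()))
    assert set(report.dispositions) == set(graph.field_index)


@pytest.mark.parametrize("seed", range(20))
def test_union_domains_match_brute_force_parent_scan(seed):
    """For every class under k parents, one property with exactly k domains."""
    text, _ = random_schema(seed, n_elements=40)
    graph = parse_schema(text)
    model, _ = convert(graph, RuleSet(containers=()))

    def structural(f):
        return f.value_kind == "complex" or (
            f.enumeration is not None and f.value_kind == "string")

    # label coherence: any name that is a class somewhere is a class everywhere
    class_labels = {upper_camel(f.name)
                    for f in graph.field_index.values() if structural(f)}
    expected: dict[str, set[str]] = {}
    for path, f in graph.field_index.items():
        label = upper_camel(f.name)
        if (structural(f) or label in class_labels) and len(path) > 1:
            parent = graph.field_index[path[:-1]]
            expected.setdefault(label, set()).add(upper_camel(parent.name))
    for label, parents in expected.items():
        prop = model.object_properties["has" + label]
        assert prop.domain == tuple(sorted(parents))
        assert prop.range == (label,)
    generated = {p for p in model.object_properties}
    assert generated == {"has" + label for label in expected}


@pytest.mark.parametrize("seed", range(10))
def test_naming_conventions_hold(seed):
    text, _ = random_schema(seed, n_elements=30)
    model, _ = convert(parse_schema(text), RuleSet(containers=()))
    for label in list(model.object_properties) + list(model.datatype_properties):
        assert label.startswith("has")
    for label in model.classes:
        assert label[0].isupper()


def test_convert_is_deterministic(toxml_mini_graph, default_rules):
    a, _ = convert(toxml_mini_graph, default_rules)
    b, _ = convert(toxml_mini_graph, default_rules)
    assert a == b


def test_load_ruleset_round_trips_default():
    rules = load_ruleset("containers: [Tests]\nrenames:\n  A/B: C\n"
                         "promotions: [A/D]\nsubclasses: [[X, Y]]\nunify: {E: F}\n")
    assert rules.containers == ("Tests",)
    assert rules.renames == {("A", "B"): "C"}
    assert rules.promotions == (("A", "D"),)
    assert rules.subclass_assertions == (("X", "Y"),)
    assert rules.label_unifications == {"E": "F"}
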