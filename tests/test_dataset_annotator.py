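"""SDF ingestion, the ot:Dataset model, annotation and harmonization."""

import pytest
from rdflib import Graph
from rdflib.compare import isomorphic

import toxlift as tx
from toxlift.dataset_annotator import dataset_to_graph
from toxlift.errors import DatasetError, SdfParseError, UnmappedValueError
from toxlift.generators import random_sdf


def test_toy_sdf_parses_with_fields_in_order():
    records = tx.read_sdf(tx.load_text("cpdbas_toy"))
    assert len(records) == 3
    for record in records:
        assert list(record.properties) == ["CASRN", "ActivityOutcome", "ChemicalName"]
        assert record.structure_block.rstrip().endswith("M  END")


def test_empty_input_gives_empty_list():
    assert tx.read_sdf("") == []
    assert tx.read_sdf("   \n") == []


def test_record_count_equals_delimiter_count():
    for name in ("cpdbas_toy", "isscan_toy"):
        text = tx.load_text(name)
        assert len(tx.read_sdf(text)) == text.count("$$$$")


def test_truncated_record_reports_index():
    text = tx.load_text("isscan_toy") + "ISS-999\n  toxlift\n\n"
    with pytest.raises(SdfParseError) as err:
        tx.read_sdf(text)
    assert err.value.record_index == 2


def test_record_counts_agree_with_rdkit():
    """Independent reader cross-check on the generated toy files."""
    rdkit_chem = pytest.importorskip("rdkit.Chem")
    text, book = random_sdf(11, n_records=12, dialect="cpdbas")
    ours = tx.read_sdf(text)
    supplier = rdkit_chem.SDMolSupplier()
    supplier.SetData(text)
    mols = [m for m in supplier]
    assert len(ours) == len(mols) == book.n_records
    assert [m.GetProp("_Name") for m in mols] == [r.identifier for r in ours]


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("dialect", ["cpdbas", "isscan"])
def test_generated_sdf_values_match_bookkeeping(seed, dialect):
    text, book = random_sdf(seed, n_records=9, dialect=dialect)
    records = tx.read_sdf(text)
    assert len(records) == book.n_records
    for record in records:
        assert record.properties == book.values[record.identifier]


def test_id_field_override():
    records = tx.read_sdf(tx.load_text("cpdbas_toy"), id_field="CASRN")
    assert [r.identifier for r in records] == ["50-00-0", "62-53-3", "64-17-5"]


def test_build_dataset_features_equal_union_of_property_keys():
    text, book = random_sdf(5, n_records=10)
    model = tx.build_dataset(tx.read_sdf(text), "http://example.org/ds/r")
    expected = set()
    for fields in book.values.values():
        expected |= set(fields)
    assert set(model.features) == expected
    assert len(model.values) == sum(len(v) for v in book.values.values())


def test_empty_record_list_gives_zero_features():
    model = tx.build_dataset([], "http://example.org/ds/empty")
    assert model.features == {} and model.values == []


def test_duplicate_identifiers_rejected():
    records = tx.read_sdf(tx.load_text("cpdbas_toy")) * 2
    with pytest.raises(DatasetError) as err:
        tx.build_dataset(records, "http://example.org/ds/dup")
    assert "CPD-001" in str(err.value)


def test_annotation_is_idempotent(toy_datasets):
    cpdbas, _ = toy_datasets
    target = "http://example.org/toxlift/endpoint#Carcinogenicity"
    once = tx.annotate_feature(cpdbas, "ActivityOutcome", target, "same_as")
    twice = tx.annotate_feature(once, "ActivityOutcome", target, "same_as")
    assert once.features["ActivityOutcome"].annotations == \
        twice.features["ActivityOutcome"].annotations == [("same_as", target)]


def test_annotating_unknown_feature_fails(toy_datasets):
    with pytest.raises(DatasetError):
        tx.annotate_feature(toy_datasets[0], "NoSuchField", "http://x", "same_as")


def test_annotation_survives_rdf_round_trip(toy_datasets, endpoint_ontology):
    cpdbas, _ = toy_datasets
    target = str(endpoint_ontology.iri("Carcinogenicity"))
    annotated = tx.annotate_feature(cpdbas, "ActivityOutcome", target, "same_as")
    again = tx.parse_dataset_rdf(tx.emit_dataset_rdf(annotated, "n3"))
    assert again.features["ActivityOutcome"].annotations == [("same_as", target)]
    assert f"owl:sameAs <{target}>" in tx.emit_dataset_rdf(annotated)


@pytest.mark.parametrize("feature,value,call", [
    ("Canc", "3", "POSITIVE"),
    ("Canc", "2", "EQUIVOCAL"),
    ("Canc", "1", "NEGATIVE"),
    ("ActivityOutcome", "active", "POSITIVE"),
    ("ActivityOutcome", "unspecified", "EQUIVOCAL"),
    ("ActivityOutcome", "inactive", "NEGATIVE"),
])
def test_default_harmonization_map(feature, value, call):
    assert tx.harmonize_call(feature, value) == call


def test_unmapped_value_errors_name_feature_and_value():
    with pytest.raises(UnmappedValueError) as err:
        tx.harmonize_call("Canc", "7")
    assert err.value.feature == "Canc" and err.value.raw_value == "7"


def test_harmonization_totality_over_declared_vocabularies():
    """Every allowed raw value maps; both dialects' positives coincide."""
    hmap = tx.default_harmonization_map()
    allowed = {"ActivityOutcome": ("active", "unspecified", "inactive"),
               "Canc": ("1", "2", "3")}
    for feature, values in allowed.items():
        for value in values:
            assert hmap.entries[(feature, value)] in ("POSITIVE", "EQUIVOCAL",
                                                      "NEGATIVE")
    assert hmap.entries[("ActivityOutcome", "active")] == \
        hmap.entries[("Canc", "3")] == "POSITIVE"


def test_map_file_round_trip_matches_default():
    loaded = tx.load_harmonization_map(tx.load_text("default_map"))
    assert loaded.entries == tx.default_harmonization_map().entries


def test_merged_query_returns_hand_enumerated_positives(toy_datasets):
    assert tx.query_merged(list(toy_datasets), call="POSITIVE") == \
        ["CPD-001", "CPD-002", "ISS-001"]
    assert tx.query_merged(list(toy_datasets), call="NEGATIVE") == \
        ["CPD-003", "ISS-002"]


def test_query_over_empty_dataset_list_is_empty():
    assert tx.query_merged([], call="POSITIVE") == []


def test_query_requires_registered_call_feature():
    model = tx.build_dataset(tx.read_sdf(tx.load_text("cpdbas_toy")),
                             "http://example.org/ds/x")
    with pytest.raises(DatasetError):
        tx.query_merged([model], call="POSITIVE")


@pytest.mark.parametrize("seed", range(6))
def test_query_equals_brute_force_filter(seed):
    text_a, _ = random_sdf(seed, n_records=15, dialect="cpdbas")
    text_b, _ = random_sdf(seed + 100, n_records=15, dialect="isscan")
    ds_a = tx.build_dataset(tx.read_sdf(text_a), "http://example.org/ds/a",
                            call_feature="ActivityOutcome")
    ds_b = tx.build_dataset(tx.read_sdf(text_b), "http://example.org/ds/b",
                            call_feature="Canc")
    hmap = tx.default_harmonization_map()
    for call in ("POSITIVE", "EQUIVOCAL", "NEGATIVE"):
        expected = [cid for ds in (ds_a, ds_b)
                    for cid, feat, val in ds.values
                    if feat == ds.call_feature
                    and hmap.entries[(feat, val)] == call]
        assert tx.query_merged([ds_a, ds_b], hmap, call) == expected


def test_emit_is_canonical_and_round_trips(toy_datasets):
    cpdbas, _ = toy_datasets
    text = tx.emit_dataset_rdf(cpdbas, "turtle")
    assert text == tx.emit_dataset_rdf(cpdbas, "turtle")
    emitted = Graph()
    emitted.parse(data=text, format="turtle")
    assert isomorphic(emitted, dataset_to_graph(cpdbas))
    again = tx.parse_dataset_rdf(text)
    assert [c.identifier for c in again.compounds] == \
        [c.identifier for c in cpdbas.compounds]
    assert sorted(again.values) == sorted(cpdbas.values)
    assert set(again.features) == set(cpdbas.features)


def test_empty_dataset_emits_header_only():
    model = tx.build_dataset([], "http://example.org/ds/empty")
    text = tx.emit_dataset_rdf(model)
    g = Graph()
    g.parse(data=text, format="turtle")
    assert len(g) == 1  # the ot:Dataset typing triple


@pytest.mark.parametrize("seed", range(5))
def test_rdf_round_trip_on_fuzzed_datasets(seed):
    text, _ = random_sdf(seed, n_records=7,
                         dialect="isscan" if seed % 2 else "cpdbas")
    model = tx.build_dataset(tx.read_sdf(text), "http://example.org/ds/f")
    again = tx.parse_dataset_rdf(tx.emit_dataset_rdf(model))
    assert sorted(again.values) == sorted(model.values)
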