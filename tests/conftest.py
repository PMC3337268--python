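import pytest

import toxlift as tx


@pytest.fixture(scope="session")
def toxml_mini_graph():
    return tx.parse_schema(tx.load_text("toxml_mini"))


@pytest.fixture(scope="session")
def default_rules():
    return tx.load_ruleset(tx.load_text("default_rules"))


@pytest.fixture(scope="session")
def converted(toxml_mini_graph, default_rules):
    """(OntologyModel, ConversionReport) for the bundled mini schema."""
    return tx.convert(toxml_mini_graph, default_rules)


@pytest.fixture(scope="session")
def endpoint_ontology():
    return tx.build_endpoint_ontology()


@pytest.fixture(scope="session")
def organs_ontology():
    return tx.build_organs_effects_ontology()


@pytest.fixture()
def toy_datasets():
    """CPDBAS-style and ISSCAN-style toy datasets with call features set."""
    cpdbas = tx.build_dataset(
        tx.read_sdf(tx.load_text("cpdbas_toy")),
        "http://example.org/ds/cpdbas", call_feature="ActivityOutcome")
    isscan = tx.build_dataset(
        tx.read_sdf(tx.load_text("isscan_toy")),
        "http://example.org/ds/isscan", call_feature="Canc")
    return cpdbas, isscan
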