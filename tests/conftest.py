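import pytest

from netprior import datasets


@pytest.fixture(scope="session")
def table1_records():
    return datasets.interaction_records()


@pytest.fixture(scope="session")
def all_records():
    return datasets.all_downstream_records()


@pytest.fixture(scope="session")
def direct_targets():
    return datasets.direct_targets()


@pytest.fixture(scope="session")
def annotation_sets():
    return list(datasets.annotation_sets())


@pytest.fixture(scope="session")
def priority_reference():
    return datasets.priority_reference()


@pytest.fixture(scope="session")
def expression_reference():
    return datasets.expression_reference()


@pytest.fixture(scope="session")
def regulator_reference():
    return datasets.regulator_reference()


@pytest.fixture(scope="session")
def causal_network():
    return datasets.causal_network()


@pytest.fixture(scope="session")
def gene_universe():
    return set(datasets.gene_universe())
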