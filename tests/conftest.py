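import pytest

from splicedex.synthetic_data import SimulationSpec, make_toy_annotation


@pytest.fixture(scope="session")
def toy():
    """Toy gene-model set plus its hand-derived event truth table."""
    models, truth = make_toy_annotation(SimulationSpec(seed=0))
    return models, truth


@pytest.fixture(scope="session")
def toy_models(toy):
    return toy[0]


@pytest.fixture(scope="session")
def truth_table(toy):
    return toy[1]
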