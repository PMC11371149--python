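import pytest

from nrcscape.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic dataset shared across tests."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def default_tree(default_dataset):
    return default_dataset.tree
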