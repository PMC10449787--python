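import pytest

from arcvir.classifier import split_train_test, train_forest
from arcvir.pipeline import features_from_dataset
from arcvir.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_ds():
    """Small labeled synthetic dataset shared across module tests."""
    return simulate_dataset(SimulationConfig(n_per_class=40, seed=11))


@pytest.fixture(scope="session")
def sim_table(sim_ds):
    return features_from_dataset(sim_ds)


@pytest.fixture(scope="session")
def trained(sim_table):
    """(model, train, test) from a stratified 70:30 split of the fixture table."""
    tr, te = split_train_test(sim_table, seed=11)
    model = train_forest(tr, n_trees=150, seed=11)
    return model, tr, te
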