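import numpy as np
import pytest

import sirnafusion as sf


@pytest.fixture(scope="session")
def nn_table():
    return sf.load_nn_table()


@pytest.fixture(scope="session")
def rule_table():
    return sf.load_rule_table()


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded synthetic dataset shared by model-level tests."""
    spec = sf.SimulationSpec(n_records=60, n_targets=6, seed=101)
    records, mrnas, truth = sf.simulate_dataset(spec)
    return records, mrnas, truth


@pytest.fixture(scope="session")
def small_features(small_dataset):
    records, mrnas, _ = small_dataset
    quant, qual = sf.featurize_records(records, mrnas)
    y = np.array([r.efficacy for r in records])
    return quant, qual, y


@pytest.fixture(scope="session")
def fitted_results(small_dataset):
    records, mrnas, _ = small_dataset
    model = sf.SirnaEfficacyModel(records, mrnas)
    return model.fit(seed=7, selection_folds=4, n_folds=5)
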