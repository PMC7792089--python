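import numpy as np
import pytest

from circrb import CircRBModel, SimConfig, TrainConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted-motif dataset shared by unit tests (n=150+150, L=40)."""
    ds, truth = simulate_dataset(SimConfig(n_pos=150, length=40, seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset):
    """A quickly fitted small model for motif/scan/model unit tests."""
    ds, _ = tiny_dataset
    model = CircRBModel(ds, n_filters=16)
    return model.fit(TrainConfig(max_epochs=12, seed=11, patience=4))
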