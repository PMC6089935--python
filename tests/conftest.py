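import numpy as np
import pytest

from obslearn import SimConfig, generate_generalization_set, generate_training_set


@pytest.fixture(scope="session")
def train_set():
    return generate_training_set(nr=20, seed=11)


@pytest.fixture(scope="session")
def gen_set(train_set):
    return generate_generalization_set(train_set, seed=12)


@pytest.fixture(scope="session")
def small_config():
    """Short trial budget for fast unit-level fits."""
    return SimConfig(seed=5, n_trials=600, snapshot_every=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
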