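import numpy as np
import pytest

from gelclust import SimulationConfig, simulate_binary_dataset


@pytest.fixture
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture
def noiseless_config():
    return SimulationConfig(flip_rate=0.0, replicate_cv=0.0, replicate_dropout=0.0, seed=11)


@pytest.fixture
def small_dataset():
    """A small planted dataset: 6 gels, 40-spot universe, 2+2 exclusive."""
    config = SimulationConfig(
        n_spots_universe=40,
        cluster_sizes=[3, 3],
        shared_spot_fraction=0.5,
        specific_spot_counts=[2, 2],
        flip_rate=0.0,
        image_shape=(256, 256),
        seed=5,
    )
    binary, truth = simulate_binary_dataset(config)
    return config, binary, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
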