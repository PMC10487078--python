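import logging

import pytest

from evbiomark import SimulationConfig, simulate_dataset

logging.getLogger("evbiomark").setLevel(logging.ERROR)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced cohort for fast module tests: 8 features/biotype, small libraries."""
    defaults = dict(
        n_features_per_biotype=8,
        lib_size_mean=5e4,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic cohort shared across module tests."""
    config = SimulationConfig(seed=11)
    cm, samples, truth = simulate_dataset(config)
    return config, cm, samples, truth


@pytest.fixture(scope="session")
def small_dataset():
    config = small_config(seed=5)
    cm, samples, truth = simulate_dataset(config)
    return config, cm, samples, truth
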