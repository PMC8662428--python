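import numpy as np
import pytest

from insolegait import data, synth


@pytest.fixture(scope="session")
def default_profiles():
    return synth.sample_profiles(16, rng_seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """4 users x 5 trials, default separation — fast enough for unit tests."""
    profiles = synth.sample_profiles(4, rng_seed=11)
    return synth.generate_dataset(profiles, n_trials=5, rng_seed=12)


@pytest.fixture(scope="session")
def full_dataset(default_profiles):
    """The study-scale layout: 16 users x 10 trials = 160 recordings."""
    return synth.generate_dataset(default_profiles, n_trials=10, rng_seed=2)


@pytest.fixture(scope="session")
def normalized_full_dataset(full_dataset):
    return [data.normalize(r) for r in full_dataset]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
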