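import numpy as np
import pytest

from entrotex import FeatureCache, generate_texture_dataset, split_information_specs


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """Four disorder-separated classes, small enough for fast pipeline tests."""
    return generate_texture_dataset(n_per_class=8, side=48, seed=11)


@pytest.fixture(scope="session")
def split_info_dataset():
    """2x2 (mean intensity) x (local disorder) fixture for fusion tests."""
    return generate_texture_dataset(split_information_specs(), n_per_class=10, side=48, seed=7)


@pytest.fixture
def cache():
    return FeatureCache()
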