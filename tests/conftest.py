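import numpy as np
import pytest

from boldmod.simulate import SimConfig, base_covariance, make_phantom_atlas


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact study configuration for unit tests: 3 bilateral pairs, short runs."""
    return SimConfig(
        dims=(16, 16, 10),
        n_region_pairs=3,
        block=3,
        n_volumes=120,
        n_volumes_task=105,
        n_subjects=2,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_atlas(small_cfg):
    return make_phantom_atlas(small_cfg)


@pytest.fixture(scope="session")
def small_labels(small_atlas):
    return small_atlas[1]


@pytest.fixture(scope="session")
def small_cov(small_cfg):
    return base_covariance(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
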