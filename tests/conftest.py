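import numpy as np
import pytest

from aposcan.pipeline import train_mapping
from aposcan.synthetic import default_world_config, generate_world
from aposcan.types import ConeCatch, ReceptorNoise


@pytest.fixture(scope="session")
def noise():
    return ReceptorNoise()


@pytest.fixture(scope="session")
def equal_noise():
    """Equal omega = 0.05 in every channel (equal abundances)."""
    return ReceptorNoise(relative_abundance={"UV": 1.0, "SW": 1.0,
                                             "MW": 1.0, "LW": 1.0},
                         weber_fraction=0.05)


@pytest.fixture(scope="session")
def mapping():
    return train_mapping(seed=0)


@pytest.fixture(scope="session")
def small_world():
    cfg = default_world_config(seed=42, honesty_slope=2.0)
    return generate_world(cfg, n_per_species=10, n_leaves=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_catch(rng, dbl=True):
    q = rng.uniform(0.05, 1.0, 4)
    return ConeCatch.from_array(q, float(rng.uniform(0.05, 1.0)) if dbl
                                else None)
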