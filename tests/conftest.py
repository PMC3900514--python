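import numpy as np
import pytest

from trawlsim.pipeline import run_pipeline
from trawlsim.synth import SyntheticWorldConfig, generate_world

SMALL_WORLD = dict(n_rows=8, n_cols=10, n_hauls=30, n_vessels=4,
                   trips_per_vessel=3, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(**SMALL_WORLD)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    """Full pipeline on the small world, shrunk net settings for speed."""
    return run_pipeline(small_bundle, mixture_n_init=3,
                        empn={"restarts": 3, "max_epochs": 200, "n_hidden": 6},
                        seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
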