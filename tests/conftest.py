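import logging

import numpy as np
import pytest

from somarsa.sheet import NoiseConfig, SomatotopyConfig, build_sheet
from somarsa.tasks import DEFAULT_RECIPES, make_task

logging.getLogger("somarsa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def body_set():
    return make_task("body")


@pytest.fixture(scope="session")
def small_config():
    """Small sheet with white, AR-free noise: fast and analytically simple."""
    return SomatotopyConfig(
        n_voxels=120,
        seed=7,
        noise=NoiseConfig(temporal_ar1=0.0, spatial_mix=0.0, scanner_sd=1.0),
    )


@pytest.fixture(scope="session")
def small_sheet(body_set, small_config):
    return build_sheet(body_set, small_config)


@pytest.fixture(scope="session")
def body_recipe():
    return DEFAULT_RECIPES["body"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
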