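import numpy as np
import pytest

from melanomap.synth import SynthConfig, gen_world

# compact world: 600 x 400 km at 25 km pixels, 12 x 8 grid of 50 km cells
SMALL_EXTENT = (0.0, 0.0, 600_000.0, 400_000.0)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=1, extent=SMALL_EXTENT, n_species=30)


@pytest.fixture(scope="session")
def small_world(small_config):
    return gen_world(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
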