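import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cgspn.colorsets import ColorSet, ProductColorSet
from cgspn.immune import build_model, default_params

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cell_colorset():
    """The (STATE, POSITION, LIFE, RECEPTOR) cellular token type."""
    state = ColorSet("STATE", ["resting", "active", "presenting", "memory", "plasma"])
    pos = ColorSet("POSITION", [0])
    life = ColorSet("LIFE", range(11))
    rec = ColorSet("RECEPTOR", range(10))
    return ProductColorSet("CELL", [state, pos, life, rec])


@pytest.fixture(scope="session")
def immune_net():
    """The default humoral model (shared: construction is cheap, reuse the compile cache)."""
    return build_model(default_params())
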