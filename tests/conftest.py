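import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tractformer3d import PhantomSpec, build_network, generate_phantom, tiny_config

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantoms32():
    """Four 32^3 phantoms with 6 tracts each (the desk-scale training set)."""
    return [generate_phantom(PhantomSpec(dims=(32, 32, 32), n_tracts=6, seed=s))
            for s in range(4)]


@pytest.fixture(scope="session")
def micro_net():
    """A small fitted-size network for shape/identity tests."""
    cfg = tiny_config(level_channels=(4, 8, 16, 16), heads_per_level=(1, 2, 4, 8),
                      blocks_per_level=(1, 1, 1, 1), out_channels=3,
                      ffn_expansion=1.5)
    return build_network(cfg, 7)


def randomize(module, rng, scale=0.3):
    """Overwrite every parameter with seeded Gaussian noise (oracle tests)."""
    for _, p in module.named_parameters():
        p.data = rng.normal(0.0, scale, p.data.shape).astype(np.float32)
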