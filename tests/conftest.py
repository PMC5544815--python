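import numpy as np
import pytest

from pbrecgi import generate_phantom, sphere_mesh


@pytest.fixture(scope="session")
def small_heart():
    """A coarse spherical epicardium shared across tests."""
    return sphere_mesh(40.0, 200)


@pytest.fixture(scope="session")
def small_phantom():
    """A small torso-heart phantom (validation exercised once here)."""
    geom = generate_phantom(heart_radius=40.0, torso_radius=120.0,
                            n_heart_nodes=200, n_torso_nodes=350,
                            n_electrodes=64, seed=7)
    geom.validate()
    return geom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
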