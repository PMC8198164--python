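import numpy as np
import pytest

from socketfit import (
    SyntheticSocketParams,
    generate_socket,
)
from socketfit.defaults import default_config, default_thresholds


@pytest.fixture(scope="session")
def socket_mesh():
    """Default synthetic socket (shared, read-only)."""
    return generate_socket()


@pytest.fixture(scope="session")
def coarse_socket():
    """Low-resolution socket for cheap deformation sweeps."""
    return generate_socket(SyntheticSocketParams(n_theta=32, n_rings=20))


@pytest.fixture(scope="session")
def cylinder_socket():
    """Circular straight cylinder: normals are exactly radial away from caps."""
    return generate_socket(
        SyntheticSocketParams(brim_a=60.0, brim_b=60.0, distal_a=60.0, distal_b=60.0,
                              n_theta=64, n_rings=30)
    )


@pytest.fixture(scope="session")
def fis_config():
    return default_config()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210528)
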