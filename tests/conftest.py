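import os

# Single-threaded BLAS before numpy loads: results must be bit-reproducible
# across machines with different core counts.
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from tippingrc.features import FeatureConfig, Trajectory
from tippingrc.systems import SystemSpec


def lorenz_rhs(state, theta):
    """Lorenz-63 with fixed sigma=10, beta=8/3; theta plays rho."""
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    return np.stack(
        [10.0 * (y - x), x * (theta - z) - y, x * y - (8.0 / 3.0) * z], axis=-1
    )


@pytest.fixture(scope="session")
def lorenz_spec():
    return SystemSpec(
        name="lorenz",
        state_names=("x", "y", "z"),
        rhs=lorenz_rhs,
        x0=np.array([1.0, 1.0, 1.0]),
        dt=0.01,
        n_steps=50000,
        theta_name="rho",
        bound=1e6,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    return FeatureConfig(k=2, s=1, poly_orders=(1, 2), post_orders=(0, 1), beta=1e-8)


@pytest.fixture
def random_traj(rng):
    return Trajectory(rng.normal(size=(40, 3)), dt=0.1)
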