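import numpy as np
import pytest

from peridmi.estimator import PriorSpec, train_estimator
from peridmi.forward_model import MicrostructureParams, default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def trained(scheme):
    """Estimator trained once at the default prior (seed 0)."""
    return train_estimator(PriorSpec(seed=0), scheme)


@pytest.fixture
def canonical_voxel():
    """One voxel at canonical diffusivities with mixed fractions."""
    return MicrostructureParams(
        v_i=0.4, v_e=0.35, v_f=0.25, orientation=np.array([0.0, 0.0, 1.0])
    )


def sphere_points(n, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
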