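import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanolem import (
    ClusterSpec,
    RddPairParams,
    generate_pair,
    make_radial_grid,
    sample_cluster,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cluster_333_7_70():
    """One packed realization of the canonical 70 nm cluster (expensive)."""
    return sample_cluster(ClusterSpec(333, 7.0, 70.0), seed=1)


@pytest.fixture(scope="session")
def noisefree_pair_70():
    """Noise-free (cluster, mixnp, wnp) triple on the 70 nm grid."""
    grid = make_radial_grid(70.0)
    params = RddPairParams.for_size_class(70, noise_rel=0.0)
    return generate_pair(grid, params, seed=11)


@pytest.fixture(scope="session")
def noisy_pair_70():
    """Default-noise triple on the 70 nm grid."""
    grid = make_radial_grid(70.0)
    params = RddPairParams.for_size_class(70)
    return generate_pair(grid, params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
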