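import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glymph_t1 as g

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SMALL_SHAPE = (32, 32, 32)


@pytest.fixture(scope="session")
def small_spec():
    """Default phantom on a coarse grid (same 18 mm FOV, 0.5625 mm voxels)."""
    return g.default_phantom_spec(SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_protocol():
    return g.default_protocol(SMALL_SHAPE)


@pytest.fixture(scope="session")
def noiseless_groups():
    return g.default_groups(noise_snr=None)


@pytest.fixture(scope="session")
def kx_group_clean(noiseless_groups):
    """KX+Gd group with jitter and noise off: planted values are exact."""
    return dataclasses.replace(noiseless_groups[1], t1_jitter_frac=0.0, c_jitter_frac=0.0)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return g.build_phantom(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
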