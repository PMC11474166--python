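import numpy as np
import pytest

from contrapet.synthetic import DEFAULT_FRAME_SCHEME, CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def frame_scheme():
    fs = np.array([f[0] for f in DEFAULT_FRAME_SCHEME])
    fe = np.array([f[1] for f in DEFAULT_FRAME_SCHEME])
    return fs, fe


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort configuration used by cross-module tests."""
    return CohortConfig.fast(
        202, n_gbm=8, n_idh=2, n_hc=6, regions_per_hemisphere=30
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


def identity_affine(voxel_mm: float = 1.0) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = voxel_mm
    return a
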