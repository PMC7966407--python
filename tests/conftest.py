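import numpy as np
import pytest

import nirsdot as nd


@pytest.fixture(scope="session")
def surface():
    return nd.generate_toy_anatomy(n_vertices=250, roi_radius_mm=10.0, seed=1)


@pytest.fixture(scope="session")
def montage(surface):
    return nd.generate_montage(surface, n_sources=4, n_detectors=8, seed=1)


@pytest.fixture(scope="session")
def sensitivity(surface, montage):
    return nd.compute_synthetic_sensitivity(surface, montage)


@pytest.fixture(scope="session")
def paradigm():
    return nd.generate_paradigm(seed=7)


@pytest.fixture(scope="session")
def small_paradigm():
    """Short run for cheap design-matrix and GLM tests."""
    return nd.generate_paradigm(
        n_trials=5, run_length_s=200.0, fs=5.0, seed=3, initial_rest_s=20.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
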