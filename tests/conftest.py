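import numpy as np
import pytest

from phenofft import AcquisitionConfig, builtin_archetypes


@pytest.fixture(scope="session")
def archetypes():
    return builtin_archetypes()


@pytest.fixture(scope="session")
def default_config():
    return AcquisitionConfig(seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A 10-cycle, 5-cell run for fast frame-rendering tests."""
    return AcquisitionConfig(seed=3, duration=0.5, pixel_size=0.5,
                             initial_cells_min=5, initial_cells_max=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_blob(rng, n=48, p_keep=0.5):
    """A random connected-ish binary blob for morphometry property tests."""
    from scipy.ndimage import gaussian_filter
    field = gaussian_filter(rng.standard_normal((n, n)), 4.0)
    blob = field > np.quantile(field, 1.0 - p_keep * 0.4)
    if blob.sum() < 20:  # pathological draw; fall back to an ellipse
        yy, xx = np.mgrid[:n, :n]
        blob = ((yy - n / 2) / (n / 3)) ** 2 + ((xx - n / 2) / (n / 4)) ** 2 <= 1
    return blob
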