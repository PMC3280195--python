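import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture(scope="session")
def texture():
    """Smooth band-limited texture suitable for MI registration."""
    rng = np.random.default_rng(42)
    coarse = ndimage.gaussian_filter(rng.normal(size=(320, 320)), 8.0)
    fine = ndimage.gaussian_filter(rng.normal(size=(320, 320)), 1.5)
    img = 0.6 * coarse / coarse.std() + 0.4 * fine / fine.std()
    img -= img.min()
    return 255.0 * img / img.max()


@pytest.fixture(scope="session")
def small_run_params():
    """Down-scaled block-registration parameters for fast tests."""
    return dict(K=4, S=48, margin=10)
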