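import numpy as np
import pytest

import sfcoupling as sf


@pytest.fixture(scope="session")
def region_set_small():
    """60 bilateral regions in 3 classes — big enough for spin tests."""
    return sf.make_region_set(60, k_classes=3, seed=42)


@pytest.fixture(scope="session")
def region_set_400():
    return sf.make_region_set(400, k_classes=5, seed=1)


@pytest.fixture(scope="session")
def smooth_field_factory(region_set_400):
    """Draws of a smooth Gaussian random field on the 400-region sphere."""
    xyz = region_set_400.xyz
    gcd = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    cov = np.exp(-0.5 * (gcd / 0.5) ** 2) + 1e-8 * np.eye(len(xyz))
    chol = np.linalg.cholesky(cov)

    def draw(rng):
        return chol @ rng.standard_normal(len(xyz))

    return draw


@pytest.fixture()
def toy_panel():
    rng = np.random.default_rng(3)
    return sf.TimeSeriesPanel(values=rng.standard_normal((5, 120)))
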