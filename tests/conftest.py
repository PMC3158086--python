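import numpy as np
import pytest

from nodulekit.config import default_config


@pytest.fixture(scope="session")
def cfg():
    """The shipped calibrated configuration (full-scale renders)."""
    return default_config()


@pytest.fixture(scope="session")
def small_cfg(cfg):
    """Reduced-scale render settings for fast unit tests."""
    return cfg.with_overrides(
        render={
            "field_size": [1600.0, 1600.0],
            "nodule_count": 8,
            "diameter_range": [80.0, 300.0],
            "pixel_size": 4.0,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)
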