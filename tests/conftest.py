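import numpy as np
import pytest

from crferad.phantom import (
    PathologyLabel,
    generate_cohort,
    generate_phantom,
    scaled_phantom_config,
)


@pytest.fixture(scope="session")
def phantom64():
    cfg = scaled_phantom_config(64, seed=7)
    return generate_phantom(cfg, PathologyLabel.from_category(6)), cfg


@pytest.fixture(scope="session")
def cohort64():
    cfg = scaled_phantom_config(64, seed=13)
    return generate_cohort(cfg, 16), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_blob(rng, side=20, smooth=2.0):
    """A random non-empty binary blob for metric tests."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(size=(side, side)), smooth)
        mask = (field > np.quantile(field, 0.75)).astype(int)
        if mask.sum() >= 3:
            return mask
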