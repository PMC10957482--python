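import numpy as np
import pytest

from lesionfm import (BackgroundParams, Encoder, EncoderConfig, LesionSpec,
                      make_classification_cohort, make_volume)
from lesionfm.pipeline import cohort_patches


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12-case, 3-class cohort on a compact grid (shared, read-only)."""
    return make_classification_cohort(
        12, K=3, rng=np.random.default_rng(7), edge_mm=48, radius_range=(4.0, 6.0))


@pytest.fixture(scope="session")
def small_patches(small_cohort):
    return cohort_patches(small_cohort, 24)


@pytest.fixture(scope="session")
def toy_encoder():
    return Encoder(EncoderConfig(), rng=np.random.default_rng(99))


@pytest.fixture
def flat_volume():
    """A constant-ish lesion volume with zero background noise."""
    spec = LesionSpec(class_id=0, radius_mm=5.0, texture_amplitude=0.0,
                      intensity_offset=100.0)
    return make_volume(spec, edge_mm=48, background=BackgroundParams(sd_hu=0.0),
                       rng=np.random.default_rng(3))
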