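import numpy as np
import pytest

from segpretext.io_preprocess import SliceSample
from segpretext.synthetic_data import PhantomConfig, cohort_slices, generate_subject


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig(seed=11)


@pytest.fixture(scope="session")
def small_cohort(phantom_config):
    """Four phantom subjects, slices keyed by subject id."""
    return cohort_slices(phantom_config, 4)


@pytest.fixture(scope="session")
def one_slice(small_cohort):
    return small_cohort["phantom-000"][1]


@pytest.fixture(scope="session")
def textured_slice():
    """A single textured-organ slice on a flat background (no noise), so the
    entropy contrast between organ and background is sharp."""
    cfg = PhantomConfig(seed=5, noise_sigma=0.0, texture_amp=0.15, warp_scale_mm=0.0)
    vol, msk = generate_subject(cfg, 0)
    return SliceSample(vol.voxels[:, :, 1], msk.voxels[:, :, 1], "tex", 1)


def _blob_mask(rng, shape, p):
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    return (field > np.quantile(field, 1 - p)).astype(np.uint8)


def random_mask_pair(rng, shape=(32, 32), p=0.3):
    """A pair of random nonempty blobby binary masks."""
    while True:
        a = _blob_mask(rng, shape, p)
        b = _blob_mask(rng, shape, p)
        if a.any() and b.any():
            return a, b
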