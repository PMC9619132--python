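import numpy as np
import pytest

import hsiseg
from hsiseg.phantom import PhantomConfig
from hsiseg.preprocess import zero_background


SMALL_BANDS = 30


@pytest.fixture(scope="session")
def small_phantom():
    """One default phantom at reduced size/bands for fast tests."""
    return hsiseg.generate_phantom(
        PhantomConfig(shape=(64, 64), band_count=SMALL_BANDS, seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return hsiseg.generate_phantom(
        PhantomConfig(shape=(48, 48), band_count=SMALL_BANDS,
                      noise_sd=0.0, illumination_gradient=0.0, seed=3))


@pytest.fixture(scope="session")
def reflectance_and_gt(small_phantom):
    """Normalized, background-zeroed reflectance cube + tumor ground truth."""
    cube = hsiseg.normalize_reflectance(small_phantom.triplet)
    cube = zero_background(cube, small_phantom.gt_tissue)
    return cube, small_phantom.gt_tumor


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
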