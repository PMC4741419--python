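import numpy as np
import pytest

from dgmpv.synthetic import (ConcentrationPattern, PhantomTruth, RegionTruth,
                             generate_phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def thalamus_phantom():
    """Noise-free single-region phantom with an identifiable gradient."""
    truth = PhantomTruth(
        regions={"thalamus": RegionTruth(1400.0, 900.0,
                                         ConcentrationPattern("radial"))},
        noise_sd=0.0, seed=0)
    return truth, generate_phantom(truth)


@pytest.fixture
def four_region_phantom():
    truth = PhantomTruth(
        regions={
            "thalamus": RegionTruth(1400.0, 900.0, ConcentrationPattern("radial")),
            "caudate": RegionTruth(1410.0, 905.0, ConcentrationPattern("constant", c0=0.6)),
            "putamen": RegionTruth(1395.0, 915.0, ConcentrationPattern("constant", c0=0.45)),
            "pallidum": RegionTruth(1340.0, 880.0, ConcentrationPattern("constant", c0=0.3)),
        },
        noise_sd=20.0, seed=7)
    return truth, generate_phantom(truth)
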