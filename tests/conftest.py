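import numpy as np
import pytest

from echogan import (
    DegradationSpec,
    DiscriminatorSpec,
    FeatureExtractor,
    GeneratorSpec,
    PhantomSpec,
    make_dataset,
)

TINY_SIDE = 32


@pytest.fixture(scope="session")
def tiny_pspec():
    return PhantomSpec(
        side_length=TINY_SIDE,
        n_inclusions=2,
        inclusion_axis_range=(3, 7),
        speckle_looks_high=4.0,
    )


@pytest.fixture(scope="session")
def tiny_dspec():
    return DegradationSpec(
        psf_sigma=1.0,
        downsample_factor=2,
        speckle_looks_low=2.0,
        contrast_gamma=1.5,
        warp_amplitude=1.0,
        warp_scale=4.0,
    )


@pytest.fixture(scope="session")
def tiny_pairs(tiny_pspec, tiny_dspec):
    return make_dataset(8, tiny_pspec, tiny_dspec, seed=7)


@pytest.fixture(scope="session")
def tiny_gspec():
    # 32-pixel images, depth 5 -> 1x1 bottleneck
    return GeneratorSpec(depth=5, base_channels=4, dropout_stages=(0,))


@pytest.fixture(scope="session")
def tiny_discspec():
    return DiscriminatorSpec(base_channels=4)


@pytest.fixture(scope="session")
def tiny_fx():
    return FeatureExtractor.random_conv(seed=0, n_stages=3, base_channels=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
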