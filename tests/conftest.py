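import numpy as np
import pytest

from balmri import (
    PhantomSpec,
    make_fixture,
    make_orthogonal_dwt_frame,
    make_sidwt_frame,
    make_tidct_frame,
)

FIXTURE_SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_complex(rng, shape):
    return rng.standard_normal(shape) + 1j * rng.standard_normal(shape)


@pytest.fixture(scope="session")
def frozen_fixture():
    """Default test fixture: 64x64 Shepp-Logan, 40% variable-density mask."""
    spec = PhantomSpec(kind="shepp_logan", shape=(64, 64), seed=FIXTURE_SEED)
    return make_fixture(spec, sampling_fraction=0.4, noise_sigma=0.0, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sidwt64():
    return make_sidwt_frame((64, 64), "db4", 3)


@pytest.fixture(scope="session")
def dwt64():
    return make_orthogonal_dwt_frame((64, 64), "db4", 3)


@pytest.fixture(scope="session")
def tidct64():
    return make_tidct_frame((64, 64), patch_size=8)
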