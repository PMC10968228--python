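import numpy as np
import pytest

from magseg.atlas import build_library
from magseg.phantom import PhantomSpec, generate_atlas_set, generate_phantom


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(shape=(48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def phantom_pair(phantom_spec):
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def atlas_pairs(phantom_pair, phantom_spec):
    return generate_atlas_set(phantom_pair, 4, phantom_spec)


@pytest.fixture(scope="session")
def library(phantom_pair, atlas_pairs):
    return build_library(phantom_pair[0], atlas_pairs, n_atlases=4,
                         dilation_radius=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
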