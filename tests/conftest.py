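import numpy as np
import pytest

from gliotrial import ModelParams, generate_synthetic_brain, seed_tumor
from gliotrial.model_core import TumorState


@pytest.fixture(scope="session")
def small_geom():
    return generate_synthetic_brain(40, 30, seed=3)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture()
def random_state(small_geom):
    """A random (unphysical but valid) state supported on the brain mask."""
    rng = np.random.default_rng(11)
    sh = small_geom.shape
    m = small_geom.mask
    return TumorState(
        P=rng.uniform(0, 1.5, sh) * m,
        I=rng.uniform(0, 1.0, sh) * m,
        B=rng.uniform(0.05, 1.0, sh) * m,
        N=rng.uniform(0, 2.0, sh) * m,
    )


@pytest.fixture()
def seeded_state(small_geom):
    return seed_tumor(small_geom)
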