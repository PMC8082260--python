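import numpy as np
import pytest

from sparsesurf.mask_io import LabelMask
from sparsesurf.phantoms import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def ellipsoid_mask() -> LabelMask:
    """A ~5 mL ellipsoid phantom on a 1 mm grid."""
    return make_phantom(PhantomSpec("ellipsoid", 5.0, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Six phantoms (two per family), kept small for fast unit tests."""
    from sparsesurf.phantoms import generate_cohort

    return generate_cohort(6, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask_pair(rng, shape=(12, 12, 12), p=0.3):
    """Two random overlapping masks on one grid (at least one voxel set)."""
    while True:
        a = (rng.random(shape) < p).astype(np.uint8)
        b = (rng.random(shape) < p).astype(np.uint8)
        if a.any() or b.any():
            return LabelMask(a), LabelMask(b)
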