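import numpy as np
import pytest

from rtplanqa.grids import DoseGrid, StructMask
from rtplanqa.synthetic import PhantomSpec, build_phantom


def random_mask(rng, shape, spacing=(1.0, 1.0, 1.0), p=0.4, name="blob"):
    """A random non-empty mask (guaranteed at least one voxel)."""
    arr = rng.random(shape) < p
    if not arr.any():
        arr[tuple(rng.integers(0, s) for s in shape)] = True
    return StructMask(name=name, values=arr, spacing=spacing)


def random_dose(rng, shape, spacing=(1.0, 1.0, 1.0), max_gy=45.0):
    return DoseGrid(values=rng.random(shape) * max_gy, spacing=spacing)


@pytest.fixture(scope="session")
def coarse_phantom():
    """A 5 mm phantom, fast enough to share across tests."""
    return build_phantom(PhantomSpec(spacing_mm=(5.0, 5.0, 5.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
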