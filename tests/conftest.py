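import numpy as np
import pytest

from pseudoct.phantom import PhantomSpec, generate_phantom
from pseudoct.physics import ScanGeometry, default_geometry


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Default desk-scale phantom population (64×64, 8 slices, 3 mm pixels)."""
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def phantom_pair(small_spec):
    """One generated (CT, activity) pair shared across read-only tests."""
    return generate_phantom(small_spec, 0)


@pytest.fixture(scope="session")
def geometry(small_spec) -> ScanGeometry:
    return default_geometry(small_spec.grid_size, small_spec.pixel_size)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
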