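import numpy as np
import pytest

from cutsim.foam import generate_porous_cloud
from cutsim.geometry import AssemblySpec, _box_solid


@pytest.fixture(scope="session")
def cube10():
    return _box_solid((10.0, 10.0, 10.0), "cube10")


@pytest.fixture(scope="session")
def dense_cloud(cube10):
    """Exact 10x10x10 lattice at 1 mm (volume fraction 1)."""
    return generate_porous_cloud(cube10, 1000.0, 1.0, seed=0)


@pytest.fixture(scope="session")
def porous_cloud(cube10):
    """Porous 400 um cloud at the 10 PCF volume fraction."""
    return generate_porous_cloud(cube10, 400.0, 0.14, seed=1)


@pytest.fixture(scope="session")
def assembly_spec():
    return AssemblySpec()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
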