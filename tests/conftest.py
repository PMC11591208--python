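import numpy as np
import pytest

from orthotrack.core import Grid3D, Volume3D
from orthotrack.phantom import PhantomConfig, generate_phantom_4dct


@pytest.fixture(scope="session")
def tiny_phantom():
    """The 64^3 test phantom (seed 17), shared across the session."""
    return generate_phantom_4dct(PhantomConfig.tiny(seed=17))


@pytest.fixture(scope="session")
def micro_phantom():
    """A very small, fast phantom for structural checks."""
    cfg = PhantomConfig.tiny(
        seed=3,
        grid=Grid3D.centered((32, 32, 32), (2.0, 2.0, 2.0)),
        tumor_radii=(8.0, 8.0, 8.0),
        tumor_center=(-14.0, 0.0, -7.0),
    )
    return generate_phantom_4dct(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_volume(rng):
    grid = Grid3D.centered((12, 10, 14), (1.5, 1.0, 2.0))
    return Volume3D(grid, rng.random(grid.shape).astype(np.float32))
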