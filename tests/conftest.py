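import numpy as np
import pytest

from perisurf import HeightMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_map(rng):
    """Levelled random rough surface, 32x32, 5 μm step."""
    z = rng.normal(0.0, 10.0, size=(32, 32))
    return HeightMap(z - z.mean(), 5.0, 5.0)


@pytest.fixture
def checkerboard():
    """±1 μm checkerboard (zero mean by construction)."""
    z = np.indices((16, 16)).sum(axis=0) % 2 * 2.0 - 1.0
    return HeightMap(z, 5.0, 5.0)


@pytest.fixture
def ramp():
    """Linear ramp from +a to -a along x, constant in y (zero mean)."""
    a = 10.0
    nr, nc = 40, 200
    x = np.linspace(a, -a, nc)
    z = np.tile(x, (nr, 1))
    return HeightMap(z - z.mean(), 5.0, 5.0)
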