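import numpy as np
import pytest

from eemtopo.surfaces import HeightMap
from eemtopo.synthetic import SurfaceGenParams, generate_surface


@pytest.fixture(scope="session")
def bone_surface() -> HeightMap:
    """A default synthetic bone-like scan (fully measured)."""
    return generate_surface(SurfaceGenParams(), seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def grid_surface(z: np.ndarray, dx: float = 0.5, dy: float | None = None, **kw) -> HeightMap:
    return HeightMap(np.asarray(z, dtype=float), dx=dx, dy=dy if dy is not None else dx, **kw)
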