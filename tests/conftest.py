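import numpy as np
import pytest

from bundlemap import PointPattern, Window, gen_poisson


@pytest.fixture
def unit_mm_window() -> Window:
    """1 mm x 1 mm analysis window (coordinates in um)."""
    return Window(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def big_window() -> Window:
    return Window(0.0, 2000.0, 0.0, 2000.0)


@pytest.fixture
def poisson_pattern(big_window) -> PointPattern:
    """A reference CSR pattern at 500 bundles/mm^2 (n ~ 2000)."""
    return gen_poisson(500.0, big_window, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
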