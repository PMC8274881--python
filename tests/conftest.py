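import numpy as np
import pytest

from lithospat import synthetic as syn
from lithospat.geometry import Window, build_pattern


@pytest.fixture(scope="session")
def unit_square():
    return Window.unit_square()


@pytest.fixture(scope="session")
def csr_pattern(unit_square):
    """One medium CSR draw reused by deterministic tests."""
    return syn.rpoispp(200, unit_square, 12345)


@pytest.fixture(scope="session")
def ds_fixture_0():
    """Session-wide synthetic site fixture (catalog, pattern)."""
    return syn.ds_fixture(0)


@pytest.fixture
def two_cluster_pattern(unit_square):
    """Fully segregated two-cluster labelled pattern (60 + 60 points)."""
    rng = np.random.default_rng(77)
    c1 = np.clip(rng.normal([0.25, 0.5], 0.06, (60, 2)), 0.001, 0.999)
    c2 = np.clip(rng.normal([0.75, 0.5], 0.06, (60, 2)), 0.001, 0.999)
    return build_pattern(
        np.vstack([c1, c2]), unit_square, {"type": ["a"] * 60 + ["b"] * 60}
    )
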