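import numpy as np
import pytest

import frispike as fs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def order6_grid():
    """Symmetric grid with P=6, lam=pi/6 (frequencies -pi/2 .. pi/2)."""
    return fs.FrequencyGrid(omega0=-np.pi / 2, lam=np.pi / 6, P=6)


@pytest.fixture(scope="session")
def order6_kernel(order6_grid):
    """Real seventh-factor E-spline reproducing e^{i omega_m t} on that grid."""
    return fs.make_espline(order6_grid.alphas)


def draw_times(rng, K, lo, hi, min_sep):
    """K strictly increasing times in [lo, hi) with pairwise gap >= min_sep."""
    for _ in range(1000):
        t = np.sort(rng.uniform(lo, hi, size=K))
        if K < 2 or np.min(np.diff(t)) >= min_sep:
            return t
    raise RuntimeError("could not place events")
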