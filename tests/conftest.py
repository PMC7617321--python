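import numpy as np
import pytest

from epipolarity import synthetic as syn


@pytest.fixture(scope="session")
def small_tissue():
    """~60-cell isotropic Voronoi epithelium used by several suites."""
    return syn.make_tissue(n_cells=60, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def circle_boundary(n=200, r=1.0):
    """Boundary points of a circle with screen-consistent angles: the
    point at parameter phi sits at on-screen angle phi from +x."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return phi, np.column_stack([r * np.cos(phi), -r * np.sin(phi)])
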