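import numpy as np
import pytest

from lsmd.mesh import TriangleMesh
from lsmd.synthetic import icosphere, make_lobe_mesh


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    v = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f)


@pytest.fixture
def icosahedron() -> TriangleMesh:
    return icosphere(0)


@pytest.fixture(scope="session")
def sphere2() -> TriangleMesh:
    """162-vertex unit sphere."""
    return icosphere(2)


@pytest.fixture(scope="session")
def sphere3() -> TriangleMesh:
    """642-vertex unit sphere."""
    return icosphere(3)


def bumpy_mesh(seed: int, subdivisions: int = 2, scale: float = 10.0
               ) -> TriangleMesh:
    """Randomly perturbed closed sphere-topology mesh for property tests."""
    rng = np.random.default_rng(seed)
    sph = icosphere(subdivisions)
    r = 1.0 + 0.2 * rng.standard_normal(sph.n_vertices)
    # smooth the radii once so the mesh stays embedded
    adj = sph.vertex_adjacency()
    r = np.array([0.5 * r[i] + 0.5 * r[nb].mean() for i, nb in enumerate(adj)])
    return TriangleMesh(sph.vertices * (scale * r)[:, None], sph.faces)


@pytest.fixture
def random_mesh() -> TriangleMesh:
    return bumpy_mesh(0)


@pytest.fixture(scope="session")
def lobe400() -> TriangleMesh:
    return make_lobe_mesh(1, 400)
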