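import numpy as np
import pytest

from meshcurve import TriangleMesh, make_icosphere, make_plane, make_pyramid


@pytest.fixture
def tetrahedron() -> TriangleMesh:
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f)


@pytest.fixture
def icosahedron() -> TriangleMesh:
    return make_icosphere(0)


@pytest.fixture
def plane_grid() -> TriangleMesh:
    return make_plane(10)


@pytest.fixture
def pyramid30() -> TriangleMesh:
    return make_pyramid(6, 30.0)


def random_bumpy_mesh(seed: int, n: int = 12) -> TriangleMesh:
    """Jittered grid with random height field: irregular but valid topology."""
    rng = np.random.default_rng(seed)
    base = make_plane(n)
    v = base.vertices.copy()
    v[:, :2] += rng.uniform(-0.3, 0.3, (v.shape[0], 2))
    v[:, 2] = rng.uniform(-1.0, 1.0, v.shape[0])
    return TriangleMesh(v, base.faces)


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
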