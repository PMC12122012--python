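import numpy as np
import pytest

from spheropack import SpherePoints, sample_uniform_sphere


@pytest.fixture(scope="session")
def tetrahedron():
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return SpherePoints(v / np.sqrt(3.0))


@pytest.fixture(scope="session")
def octahedron():
    v = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    return SpherePoints(v)


@pytest.fixture(scope="session")
def cube():
    v = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    return SpherePoints(v / np.sqrt(3.0))


@pytest.fixture(scope="session")
def icosahedron():
    phi = (1 + np.sqrt(5.0)) / 2
    v = np.array(
        [
            [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
            [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
            [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
        ],
        dtype=float,
    )
    return SpherePoints(v / np.linalg.norm(v, axis=1, keepdims=True))


@pytest.fixture(scope="session")
def uniform_100():
    return sample_uniform_sphere(100, seed=42)


def random_rotation(seed):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
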