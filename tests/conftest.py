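import numpy as np
import pytest

from budmorph import mesh as M


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def icosphere1():
    return M.build_icosphere(1, 1.0)


@pytest.fixture(scope="session")
def icosphere2():
    return M.build_icosphere(2, 1.0)


@pytest.fixture
def budded_sphere():
    """Unit icosphere (subdivision 2) with a 0.5 rad bud cap about +z."""
    m = M.build_icosphere(2, 1.0)
    M.init_bud_patch(m, [0.0, 0.0, 1.0], 0.5)
    m.set_rest_state_from_geometry()
    return m


@pytest.fixture
def perturbed_sphere(rng):
    """Subdivision-1 sphere with rest state of the sphere but jittered
    positions, so every elastic term is strained."""
    m = M.build_icosphere(1, 1.0)
    m.vertices = m.vertices + 0.02 * rng.standard_normal(m.vertices.shape)
    return m


def two_triangle_patch():
    """Open strip of two triangles sharing an interior edge (0-1)."""
    verts = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, 0.9, 0.0],
        [0.5, -0.9, 0.1],
    ])
    faces = np.array([[0, 1, 2], [1, 0, 3]])
    m = M.SurfaceMesh(verts, faces)
    m.set_rest_state_from_geometry()
    return m
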