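import itertools

import numpy as np
import pytest

from ssamfe.mesh import DensityField, TetMesh
from ssamfe.synthfem import FamilySpec, generate_family

# 6-tet split of a hexahedron, conforming across a structured grid
_HEX_TETS = [(0, 1, 3, 7), (0, 1, 7, 5), (0, 5, 7, 4),
             (0, 3, 2, 7), (0, 2, 6, 7), (0, 6, 4, 7)]


def structured_box(nx, ny, nz, size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Structured tet mesh of an axis-aligned box (6 tets per cell)."""
    sx, sy, sz = size
    xs = origin[0] + np.linspace(0, sx, nx + 1)
    ys = origin[1] + np.linspace(0, sy, ny + 1)
    zs = origin[2] + np.linspace(0, sz, nz + 1)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    elems = []
    for i, j, k in itertools.product(range(nx), range(ny), range(nz)):
        v = [nid(i, j, k), nid(i + 1, j, k), nid(i, j + 1, k),
             nid(i + 1, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
             nid(i, j + 1, k + 1), nid(i + 1, j + 1, k + 1)]
        for t in _HEX_TETS:
            elems.append([v[x] for x in t])
    return TetMesh(nodes, np.array(elems))


def random_tet(rng, scale=10.0, min_volume=1e-3):
    """A random non-degenerate tetrahedron's 4 points."""
    while True:
        pts = rng.uniform(-scale, scale, (4, 3))
        if abs(np.linalg.det(pts[1:] - pts[0])) / 6.0 > min_volume:
            return pts


@pytest.fixture
def unit_tet():
    return TetMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        np.array([[0, 1, 2, 3]]),
    )


@pytest.fixture
def two_tets():
    """Two tets sharing the facet (0, 1, 2)."""
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                      [0.3, 0.3, -1.0]])
    return TetMesh(nodes, np.array([[0, 1, 2, 3], [0, 1, 2, 4]]))


@pytest.fixture(scope="session")
def small_family_spec():
    return FamilySpec(n_members=9, seed=11, n_axial=14, n_ring=2, n_theta=8)


@pytest.fixture(scope="session")
def small_family(small_family_spec):
    """A small corresponded synthetic family: 8 training + 1 held-out."""
    members, latents = generate_family(small_family_spec)
    return members, latents


@pytest.fixture(scope="session")
def femur_member(small_family):
    members, _ = small_family
    return members[0]


def uniform_density(mesh, rho=1.0, kind="rho_app"):
    return DensityField(np.full(mesh.n_elements, rho), kind=kind)
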