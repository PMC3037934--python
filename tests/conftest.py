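"""Shared fixtures: small generated meshes and canonical load scenarios."""

import numpy as np
import pytest

from thermograde import (
    LoadCase,
    ProbeSet,
    SeedSet,
    TetMesh,
    face_traction_forces,
    make_bar,
    make_skull_like_shell,
)


@pytest.fixture
def unit_tet() -> TetMesh:
    """The reference tetrahedron with volume 1/6."""
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return TetMesh(coords, np.array([[0, 1, 2, 3]]))


@pytest.fixture
def small_bar() -> TetMesh:
    return make_bar(L=1.0, W=1.0, H=1.0, nx=4, ny=2, nz=2)


@pytest.fixture
def cubic_cell_bar() -> TetMesh:
    """Bar whose hex cells are cubes (nonobtuse Kuhn tets -> M-matrix)."""
    return make_bar(L=1.0, W=0.25, H=0.25, nx=8, ny=2, nz=2)


@pytest.fixture(scope="session")
def shell() -> TetMesh:
    return make_skull_like_shell(refinement=1)


@pytest.fixture
def shell_scenario(shell):
    """Clamped-base shell with a lateral point load at the apex, plus probes."""
    base = shell.nodes_on_plane(axis=2, value=0.0)
    apex = shell.locate_nearest_node([0.0, 0.0, 0.05])
    loads = LoadCase.fix_nodes(base).merged_with(
        LoadCase(point_forces=[(apex, np.array([5.0, 0.0, -10.0]))])
    )
    # probes at centroids of a few elements spread over both regions
    idx = [0, shell.n_tets // 3, shell.n_tets // 2, shell.n_tets - 1]
    probes = ProbeSet(
        labels=[f"site{i}" for i in range(len(idx))],
        points=shell.centroids()[idx],
    )
    return shell, loads, probes


def axial_bar_loadcase(mesh: TetMesh, L: float, F: float = 1.0) -> LoadCase:
    """Clamp the x=0 face; apply total axial force F as uniform end traction."""
    area = 1.0
    for axis in (1, 2):
        area_extent = mesh.node_coords[:, axis].max() - mesh.node_coords[:, axis].min()
        area *= area_extent
    tip_nodes = mesh.nodes_on_plane(axis=0, value=L)
    traction = face_traction_forces(mesh, tip_nodes, [F / area, 0.0, 0.0])
    clamp = LoadCase.fix_nodes(mesh.nodes_on_plane(axis=0, value=0.0))
    return traction.merged_with(clamp)


def tip_displacement(mesh: TetMesh, u: np.ndarray, L: float) -> float:
    """Mean axial displacement of the x = L face."""
    tip = mesh.nodes_on_plane(axis=0, value=L)
    return float(u[tip, 0].mean())


@pytest.fixture
def two_seed_bar(cubic_cell_bar):
    mesh = cubic_cell_bar
    n0 = mesh.locate_nearest_node([0.0, 0.125, 0.125])
    n1 = mesh.locate_nearest_node([1.0, 0.125, 0.125])
    return mesh, SeedSet([n0, n1], [10.0, 90.0])
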