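"""Programmatic test geometries and analytic oracles.

Every mesh in the test suite is generated here, deterministically, so the
package ships no mesh data.  The structured bar uses the 6-tet Kuhn split of
each hex cell: all six tets share the cell's main diagonal, so adjacent
cells conform face-to-face without parity alternation.  The hemispherical
shell is a desk-scale stand-in for cranial geometry (synthetic — it is not
derived from any scanned skull): a cortical shell over a trabecular core,
built by radially mapping a structured half-cube onto the half-ball.
"""

from __future__ import annotations

import numpy as np

from .mesh import TetMesh

#: Kuhn subdivision of the unit hex (corner bit order x, y, z): six tets
#: around the 0 -> 7 main diagonal, one per permutation of the axis walk.
_KUHN_TETS = (
    (0, 1, 3, 7),
    (0, 1, 5, 7),
    (0, 2, 3, 7),
    (0, 2, 6, 7),
    (0, 4, 5, 7),
    (0, 4, 6, 7),
)


def _structured_box(
    lo: np.ndarray, hi: np.ndarray, nx: int, ny: int, nz: int
) -> tuple[np.ndarray, np.ndarray]:
    """Node grid and 6-tet-per-cell connectivity of an axis-aligned box."""
    xs = np.linspace(lo[0], hi[0], nx + 1)
    ys = np.linspace(lo[1], hi[1], ny + 1)
    zs = np.linspace(lo[2], hi[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = [
                    nid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                    for b in range(8)
                ]
                for t in _KUHN_TETS:
                    tets.append([corner[v] for v in t])
    return coords, np.array(tets, dtype=np.intp)


def make_bar(
    L: float = 1.0,
    W: float = 1.0,
    H: float = 1.0,
    nx: int = 4,
    ny: int = 2,
    nz: int = 2,
    region: str = "default",
) -> TetMesh:
    """Structured bar [0,L]×[0,W]×[0,H] with 6 tets per hex cell.

    Node count (nx+1)(ny+1)(nz+1); tet count 6·nx·ny·nz; total volume L·W·H
    exactly (the Kuhn split tiles each cell).
    """
    if min(L, W, H) <= 0 or min(nx, ny, nz) < 1:
        raise ValueError("bar dimensions must be positive and subdivisions >= 1")
    coords, tets = _structured_box(np.zeros(3), np.array([L, W, H]), nx, ny, nz)
    return TetMesh(coords, tets, np.full(len(tets), region, dtype=object))


def make_two_region_bar(
    L: float = 1.0,
    nx: int = 4,
    split_fraction: float = 0.5,
    W: float = 1.0,
    H: float = 1.0,
    ny: int = 1,
    nz: int = 1,
    labels: tuple[str, str] = ("stiff", "compliant"),
) -> TetMesh:
    """Bar partitioned at x = split_fraction·L into two labelled regions.

    The split must land on a cell boundary so regions tile whole elements.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be strictly between 0 and 1")
    cells = split_fraction * nx
    if abs(cells - round(cells)) > 1e-9:
        raise ValueError(
            f"split_fraction {split_fraction} does not fall on a cell boundary "
            f"(nx = {nx}); choose a multiple of 1/{nx}"
        )
    mesh = make_bar(L, W, H, nx, ny, nz)
    x_split = split_fraction * L
    cx = mesh.centroids()[:, 0]
    regions = np.where(cx < x_split, labels[0], labels[1]).astype(object)
    return TetMesh(mesh.node_coords, mesh.tets, regions)


def graded_bar_tip_displacement(
    F: float = 1.0, A: float = 1.0, L: float = 1.0, E0: float = 1.0, E1: float = 2.0
) -> float:
    """Closed-form tip displacement of an axially loaded bar with linear E(x).

    With E(x) = E0 + (E1 − E0) x / L and constant stress sigma = F / A,
    u(L) = ∫ sigma / E dx = F·L / (A·(E1 − E0)) · ln(E1 / E0); the E1 → E0
    limit recovers the uniform-bar formula F·L / (A·E0).
    """
    if E0 <= 0 or E1 <= 0:
        raise ValueError("moduli must be positive")
    if np.isclose(E0, E1, rtol=1e-12):
        return F * L / (A * E0)
    return F * L / (A * (E1 - E0)) * float(np.log(E1 / E0))


def make_skull_like_shell(
    R_outer: float = 0.05,
    R_inner: float = 0.025,
    refinement: int = 2,
    labels: tuple[str, str] = ("cortical", "trabecular"),
) -> TetMesh:
    """Synthetic hemispherical two-region shell (flat face on z = 0).

    A structured half-cube grid is mapped radially onto the half-ball of
    radius ``R_outer`` (cube-to-ball mapping p → p·‖p‖_∞/‖p‖₂), then each
    tet is labelled cortical or trabecular by its centroid radius against
    ``R_inner``.  Deterministic; node set mirror-symmetric across x = 0 and
    y = 0.  The map sends ‖·‖_∞ level sets to spheres, so whenever
    R_inner/R_outer is a multiple of 1/(4·refinement) — as with the
    defaults — the cortical/trabecular interface is resolved exactly by the
    grid; the outer surface is always faceted, so volumes approach the
    analytic hemisphere values only under refinement.
    """
    if not 0 < R_inner < R_outer:
        raise ValueError("need 0 < R_inner < R_outer")
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    n = 8 * refinement
    coords, tets = _structured_box(
        np.array([-1.0, -1.0, 0.0]), np.array([1.0, 1.0, 1.0]), n, n, n // 2
    )
    linf = np.max(np.abs(coords), axis=1)
    l2 = np.linalg.norm(coords, axis=1)
    scale = np.ones(len(coords))
    nz = l2 > 0
    scale[nz] = linf[nz] / l2[nz]
    mapped = coords * (scale * R_outer)[:, None]
    mesh = TetMesh(mapped, tets)  # validation reorients any inverted tets
    radii = np.linalg.norm(mesh.centroids(), axis=1)
    regions = np.where(radii >= R_inner, labels[0], labels[1]).astype(object)
    return TetMesh(mesh.node_coords, mesh.tets, regions)


def hemisphere_region_volumes(R_outer: float, R_inner: float) -> tuple[float, float]:
    """Analytic (shell, core) volumes of the hemispherical two-region fixture."""
    half = 2.0 * np.pi / 3.0
    return half * (R_outer**3 - R_inner**3), half * R_inner**3
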