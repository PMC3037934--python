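"""Linear isotropic elasticity on tetrahedral meshes with graded modulus.

Pure displacement formulation with 4-node linear tets: the strain-
displacement operator B is constant within each element, so the element
stiffness is B^T C(E, nu) B V evaluated at the element's quadrature modulus.
A linearly varying modulus is therefore integrated exactly by the one-point
(centroid) rule.  No locking mitigation is applied; with nu <= 0.36
throughout the bundled property table, volumetric locking stays mild.

Three material modes mirror the grading workflow:

* ``uniform_isotropic`` — cortical (17.3 GPa, 0.28) / trabecular
  (0.64 GPa, 0.28) split by region name;
* ``regional_isotropic`` — each tet takes its region's table row;
* ``thermally_graded`` — conduction solve → modulus map → per-element
  modulus, trabecular regions optionally kept at their discrete value.

Thermal expansion is identically zero: temperature acts purely as the
modulus surrogate and induces no strain of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import grading, thermal
from .grading import GPA, ModulusTemperatureMap, RegionTable, element_modulus
from .mesh import TetMesh
from .thermal import SeedSet, SolverError, ThermalProps, apply_dirichlet, _solve_spd

#: uniform-isotropic defaults: (E Pa, nu) for cortical and trabecular bone
UNIFORM_CORTICAL = (17.3 * GPA, 0.28)
UNIFORM_TRABECULAR = (0.64 * GPA, 0.28)

#: region names treated as trabecular bone in the uniform/graded modes
TRABECULAR_NAMES = frozenset({"trabecular", "trabecular bone"})

_AXES = {"x": 0, "y": 1, "z": 2, "0": 0, "1": 1, "2": 2}


def is_trabecular(region: str) -> bool:
    return str(region).strip().lower() in TRABECULAR_NAMES


@dataclass
class LoadCase:
    """Point forces and single-axis prescribed displacements.

    ``point_forces``: list of (node index, length-3 force vector in N).
    ``fixed_dofs``: list of (node index, axis 0/1/2, prescribed value in m).
    A node may not carry both a force and a constraint on the same axis.
    """

    point_forces: list[tuple[int, np.ndarray]] = field(default_factory=list)
    fixed_dofs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for nid, axis, _ in self.fixed_dofs:
            if (nid, axis) in seen:
                raise ValueError(f"dof (node {nid}, axis {axis}) constrained twice")
            seen.add((nid, axis))
        for nid, f in self.point_forces:
            f = np.asarray(f, dtype=float)
            for axis in range(3):
                if f[axis] != 0.0 and (nid, axis) in seen:
                    raise ValueError(
                        f"node {nid} axis {axis} carries both a force and a fixed displacement"
                    )

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        for nid, vec in self.point_forces:
            f[3 * nid : 3 * nid + 3] += np.asarray(vec, dtype=float)
        return f

    def fixed_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([3 * nid + axis for nid, axis, _ in self.fixed_dofs], dtype=np.intp)
        vals = np.array([v for _, _, v in self.fixed_dofs], dtype=float)
        order = np.argsort(idx)
        return idx[order], vals[order]

    @classmethod
    def fix_nodes(cls, node_ids, value: float = 0.0) -> "LoadCase":
        """Fully clamp the given nodes (all three axes)."""
        return cls(
            fixed_dofs=[(int(n), a, value) for n in np.atleast_1d(node_ids) for a in range(3)]
        )

    def merged_with(self, other: "LoadCase") -> "LoadCase":
        return LoadCase(
            point_forces=self.point_forces + other.point_forces,
            fixed_dofs=self.fixed_dofs + other.fixed_dofs,
        )


def isotropic_elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6×6 isotropic stiffness in Voigt order (xx, yy, zz, xy, yz, zx)."""
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson's ratio must satisfy 0 <= nu < 0.5, got {nu}")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    C[np.arange(3, 6), np.arange(3, 6)] = mu
    return C


def element_b_matrices(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Constant strain-displacement operators B (n_tets, 6, 12) and volumes.

    Voigt rows (eps_xx, eps_yy, eps_zz, gamma_xy, gamma_yz, gamma_zx) with
    engineering shear; columns ordered (ux, uy, uz) per local node.
    """
    grads, vols = mesh.shape_gradients()
    n = mesh.n_tets
    B = np.zeros((n, 6, 12))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    for a in range(4):
        c = 3 * a
        B[:, 0, c] = gx[:, a]
        B[:, 1, c + 1] = gy[:, a]
        B[:, 2, c + 2] = gz[:, a]
        B[:, 3, c] = gy[:, a]
        B[:, 3, c + 1] = gx[:, a]
        B[:, 4, c + 1] = gz[:, a]
        B[:, 4, c + 2] = gy[:, a]
        B[:, 5, c] = gz[:, a]
        B[:, 5, c + 2] = gx[:, a]
    return B, vols


def assemble_stiffness(
    mesh: TetMesh,
    E_per_element: np.ndarray,
    nu: np.ndarray | float = 0.28,
) -> sp.csr_array:
    """Assemble the global stiffness matrix (3 n_nodes square, symmetric).

    ``E_per_element`` is either (n_tets,) — one modulus per element — or
    (n_tets, 4) quadrature values, averaged (the stiffness is linear in E and
    B is constant, so the average integrates the graded stiffness exactly).
    ``nu`` is a scalar, a per-element array, or a nodal field (averaged per
    element).
    """
    E_per_element = np.asarray(E_per_element, dtype=float)
    if E_per_element.ndim == 2:
        E_per_element = E_per_element.mean(axis=1)
    if len(E_per_element) != mesh.n_tets:
        raise ValueError("need one modulus (or quadrature set) per element")
    if np.any(E_per_element <= 0):
        bad = int(np.nonzero(E_per_element <= 0)[0][0])
        raise ValueError(f"element {bad}: modulus must be positive, got {E_per_element[bad]:g}")

    nu_arr = np.asarray(nu, dtype=float)
    if nu_arr.ndim == 0:
        nu_e = np.full(mesh.n_tets, float(nu_arr))
    elif len(nu_arr) == mesh.n_tets:
        nu_e = nu_arr
    elif len(nu_arr) == mesh.n_nodes:
        nu_e = nu_arr[mesh.tets].mean(axis=1)
    else:
        raise ValueError("nu must be scalar, per-element, or per-node")
    if np.any(nu_e < 0) or np.any(nu_e >= 0.5):
        bad = int(np.nonzero((nu_e < 0) | (nu_e >= 0.5))[0][0])
        raise ValueError(
            f"element {bad}: Poisson's ratio must satisfy 0 <= nu < 0.5, got {nu_e[bad]:g}"
        )

    B, vols = element_b_matrices(mesh)
    lam = E_per_element * nu_e / ((1.0 + nu_e) * (1.0 - 2.0 * nu_e))
    mu = E_per_element / (2.0 * (1.0 + nu_e))
    C = np.zeros((mesh.n_tets, 6, 6))
    C[:, :3, :3] = lam[:, None, None]
    idx = np.arange(3)
    C[:, idx, idx] += 2.0 * mu[:, None]
    C[:, idx + 3, idx + 3] = mu[:, None]
    ke = np.einsum("e,eia,eij,ejb->eab", vols, B, C, B, optimize=True)

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(
        mesh.n_tets, 12
    )
    rows = np.repeat(dofs, 12, axis=1).reshape(-1)
    cols = np.tile(dofs, (1, 12)).reshape(-1)
    n_dof = 3 * mesh.n_nodes
    return sp.coo_array((ke.reshape(-1), (rows, cols)), shape=(n_dof, n_dof)).tocsr()


def solve_displacements(K: sp.csr_array, loads: LoadCase, n_nodes: int) -> np.ndarray:
    """Solve K u = f under the load case; returns (n_nodes, 3) displacements.

    Constraints are eliminated (exact prescribed values); the reduced system
    must be SPD — an under-constrained model (remaining rigid-body modes)
    raises :class:`SolverError`.
    """
    if not loads.fixed_dofs:
        raise SolverError(
            "no constraints given: the stiffness matrix is singular "
            "(6 rigid-body modes); fix at least enough dofs to remove them"
        )
    f = loads.force_vector(n_nodes)
    fixed_idx, fixed_vals = loads.fixed_arrays()
    K_ff, rhs, free = apply_dirichlet(K, fixed_idx, fixed_vals)
    rhs = rhs + f[free]
    u = np.empty(3 * n_nodes)
    u[fixed_idx] = fixed_vals
    try:
        x = _solve_spd(K_ff, rhs, n_nodes)
    except Exception as exc:  # umfpack/superlu raise on exact singularity
        raise SolverError(
            "reduced stiffness system is singular — constraints do not remove "
            "all rigid-body modes"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise SolverError(
            "reduced stiffness system is singular — constraints do not remove "
            "all rigid-body modes"
        )
    u[free] = x
    return u.reshape(n_nodes, 3)


def face_traction_forces(mesh: TetMesh, face_nodes: np.ndarray, traction: np.ndarray) -> LoadCase:
    """Equivalent nodal forces for a uniform traction (N/m²) on boundary faces.

    ``face_nodes`` selects the boundary faces whose three nodes all lie in
    it; each face spreads traction × area equally over its three nodes
    (exact lumping for constant traction on linear triangles).
    """
    sel = set(int(n) for n in np.atleast_1d(face_nodes))
    faces, _ = mesh.boundary_faces()
    traction = np.asarray(traction, dtype=float)
    forces: dict[int, np.ndarray] = {}
    for tri in faces:
        if all(int(v) in sel for v in tri):
            p = mesh.node_coords[tri]
            area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
            for v in tri:
                forces.setdefault(int(v), np.zeros(3))
                forces[int(v)] += traction * area / 3.0
    return LoadCase(point_forces=[(nid, f) for nid, f in sorted(forces.items())])


# ------------------------------------------------------------ material modes

def _regional_properties(mesh: TetMesh, table: RegionTable) -> tuple[np.ndarray, np.ndarray]:
    E = np.empty(mesh.n_tets)
    nu = np.empty(mesh.n_tets)
    for region in mesh.region_labels:
        m = np.array([str(r) == region for r in mesh.region_of_tet])
        E[m] = table.modulus(region)
        nu[m] = table.poisson(region)
    return E, nu


@dataclass
class MaterialModeResult:
    """Outputs of one material-mode run."""

    mode: str
    displacements: np.ndarray          # (n_nodes, 3), meters
    E_per_element: np.ndarray          # Pa
    nu_per_element: np.ndarray
    temperature: np.ndarray | None = None   # nodal field, graded mode only
    E_nodal: np.ndarray | None = None       # nodal modulus field, graded mode only


def run_material_mode(
    mesh: TetMesh,
    mode: str,
    loads: LoadCase,
    table: RegionTable | None = None,
    seeds: SeedSet | None = None,
    emap: ModulusTemperatureMap | None = None,
    thermal_props: ThermalProps | None = None,
    nu_policy: float | str = 0.28,
    grade_trabecular: bool = False,
) -> MaterialModeResult:
    """Solve the structural problem under one of the three material models.

    Parameters
    ----------
    mode : {"uniform_isotropic", "regional_isotropic", "thermally_graded"}
    nu_policy : Poisson's-ratio policy for the graded mode — a global
        constant (default 0.28) or ``"regional"`` to take each tet's table row.
    grade_trabecular : when False (default), regions whose name marks them as
        trabecular bone keep the discrete trabecular properties instead of
        the graded field.
    """
    temperature = None
    E_nodal = None
    if mode == "uniform_isotropic":
        E = np.empty(mesh.n_tets)
        nu = np.empty(mesh.n_tets)
        trab = np.array([is_trabecular(r) for r in mesh.region_of_tet])
        E[~trab], nu[~trab] = UNIFORM_CORTICAL
        E[trab], nu[trab] = UNIFORM_TRABECULAR
    elif mode == "regional_isotropic":
        if table is None:
            raise ValueError("regional_isotropic mode requires a material table")
        E, nu = _regional_properties(mesh, table)
    elif mode == "thermally_graded":
        if seeds is None:
            raise ValueError("thermally_graded mode requires a seed set")
        emap = emap or ModulusTemperatureMap()
        temperature = thermal.solve_steady_state(mesh, seeds, thermal_props)
        E_nodal = grading.temperature_to_modulus_field(temperature, emap)
        E = element_modulus(mesh, E_nodal, rule="centroid")
        if isinstance(nu_policy, str):
            if nu_policy != "regional":
                raise ValueError(f"unknown nu policy {nu_policy!r}")
            if table is None:
                raise ValueError("nu_policy='regional' requires a material table")
            _, nu = _regional_properties(mesh, table)
        else:
            nu = np.full(mesh.n_tets, float(nu_policy))
        if not grade_trabecular:
            trab = np.array([is_trabecular(r) for r in mesh.region_of_tet])
            E[trab], nu[trab] = UNIFORM_TRABECULAR
    else:
        raise ValueError(f"unknown material mode {mode!r}")

    K = assemble_stiffness(mesh, E, nu)
    u = solve_displacements(K, loads, mesh.n_nodes)
    return MaterialModeResult(
        mode=mode, displacements=u, E_per_element=E, nu_per_element=nu,
        temperature=temperature, E_nodal=E_nodal,
    )


# ------------------------------------------------------------------- CSV I/O

def read_loads_csv(path: str | Path, mesh: TetMesh) -> LoadCase:
    """Point forces from CSV: (node_id | x,y,z, fx, fy, fz)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    ids = _resolve_node_ids(df, cols, mesh, path)
    try:
        f = df[[cols["fx"], cols["fy"], cols["fz"]]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{path}: loads CSV needs fx, fy, fz columns") from exc
    return LoadCase(point_forces=[(int(n), f[i]) for i, n in enumerate(ids)])


def read_constraints_csv(path: str | Path, mesh: TetMesh) -> LoadCase:
    """Prescribed displacements from CSV: (node_id | x,y,z, axis, value).

    ``axis`` accepts x/y/z/0/1/2 or ``all`` to clamp every axis.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    ids = _resolve_node_ids(df, cols, mesh, path)
    if "axis" not in cols:
        raise ValueError(f"{path}: constraints CSV needs an 'axis' column")
    values = (
        df[cols["value"]].to_numpy(dtype=float) if "value" in cols else np.zeros(len(df))
    )
    fixed: list[tuple[int, int, float]] = []
    for i, nid in enumerate(ids):
        ax = str(df[cols["axis"]].iloc[i]).strip().lower()
        axes = (0, 1, 2) if ax == "all" else (_AXES[ax],)
        for a in axes:
            fixed.append((int(nid), a, float(values[i])))
    return LoadCase(fixed_dofs=fixed)


def _resolve_node_ids(df: pd.DataFrame, cols: dict, mesh: TetMesh, path) -> np.ndarray:
    if "node_id" in cols:
        return df[cols["node_id"]].to_numpy(dtype=np.intp)
    if {"x", "y", "z"} <= cols.keys():
        pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        return np.array([mesh.locate_nearest_node(p) for p in pts], dtype=np.intp)
    raise ValueError(f"{path}: CSV needs either a 'node_id' column or 'x','y','z' columns")
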