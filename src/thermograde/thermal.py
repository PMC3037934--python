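"""Steady-state heat conduction on tetrahedral meshes.

The temperature field here is a surrogate: fixing "temperatures" at seed
nodes and solving Laplace's equation spatially interpolates sparse material
measurements along conduction paths through the structure.  All exterior
faces without seeds are insulated (natural boundary condition), so the only
data entering the solution are the seed values — which is why the solution
is invariant to uniformly rescaling the conductivity.

Seed constraints are imposed by row/column elimination with a load-vector
correction, so seed nodes carry their prescribed values to machine precision
and the reduced system stays symmetric positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .mesh import TetMesh

#: switch from direct factorization to preconditioned CG above this size
_DIRECT_SOLVER_MAX_NODES = 200_000
#: relative residual tolerance shared by both solver paths
SOLVER_RTOL = 1e-10


class SolverError(RuntimeError):
    """Raised when a linear system cannot be solved as posed."""


@dataclass
class SeedSet:
    """Dirichlet seed constraints: node indices with prescribed temperatures.

    ``patch_radius`` > 0 extends each seed to every node within that radius,
    which regularises the otherwise mesh-dependent point constraint.
    """

    node_ids: np.ndarray
    temperatures: np.ndarray
    patch_radius: float = 0.0

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.intp).reshape(-1)
        self.temperatures = np.asarray(self.temperatures, dtype=float).reshape(-1)
        if len(self.node_ids) == 0:
            raise ValueError("seed set must contain at least one entry")
        if len(self.node_ids) != len(self.temperatures):
            raise ValueError("one temperature per seed node required")
        uniq, first = np.unique(self.node_ids, return_index=True)
        if len(uniq) != len(self.node_ids):
            # duplicates are tolerated only when the values agree
            for nid in uniq:
                vals = self.temperatures[self.node_ids == nid]
                if np.ptp(vals) > 0:
                    raise ValueError(f"conflicting temperatures for seed node {nid}")
            self.node_ids = uniq
            self.temperatures = self.temperatures[first]

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self.temperatures.min()), float(self.temperatures.max())

    def expand_patches(self, mesh: TetMesh) -> "SeedSet":
        """Resolve patch seeds to an equivalent plain node seed set."""
        if self.patch_radius <= 0:
            return self
        ids, temps = [], []
        for nid, t in zip(self.node_ids, self.temperatures):
            d = np.linalg.norm(mesh.node_coords - mesh.node_coords[nid], axis=1)
            within = np.nonzero(d <= self.patch_radius)[0]
            ids.extend(within)
            temps.extend([t] * len(within))
        return SeedSet(np.array(ids), np.array(temps))


@dataclass
class ThermalProps:
    """Per-region thermal conductivity in W/(m·K); defaults to 1.0 everywhere.

    The steady-state solution with pure Dirichlet/insulated boundaries does
    not depend on a uniform rescaling of k, so the default is arbitrary.
    """

    conductivity_of_region: dict[str, float] = field(default_factory=dict)
    default_conductivity: float = 1.0

    def __post_init__(self) -> None:
        for region, k in self.conductivity_of_region.items():
            if not k > 0:
                raise ValueError(f"conductivity for region {region!r} must be positive, got {k}")
        if not self.default_conductivity > 0:
            raise ValueError("default conductivity must be positive")

    def per_element(self, mesh: TetMesh) -> np.ndarray:
        return np.array(
            [
                self.conductivity_of_region.get(str(r), self.default_conductivity)
                for r in mesh.region_of_tet
            ]
        )


def assemble_conduction_system(mesh: TetMesh, props: ThermalProps | None = None) -> sp.csr_array:
    """Assemble the conduction stiffness matrix K_T (n_nodes × n_nodes).

    Element contribution: k_e * V_e * G G^T with G the (4, 3) matrix of
    shape-function gradients.  Row sums are zero — constants are in the
    nullspace until Dirichlet seeds are imposed.
    """
    props = props or ThermalProps()
    k_elem = props.per_element(mesh)
    grads, vols = mesh.shape_gradients()
    ke = np.einsum("e,eai,ebi->eab", k_elem * vols, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_array(
        (ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


def _solve_spd(K_ff: sp.csr_array, rhs: np.ndarray, n_nodes: int) -> np.ndarray:
    if K_ff.shape[0] == 0:
        return np.empty(0)
    if n_nodes <= _DIRECT_SOLVER_MAX_NODES:
        return spla.spsolve(K_ff.tocsc(), rhs)
    M = sp.diags_array(1.0 / K_ff.diagonal())
    x, info = spla.cg(K_ff, rhs, rtol=SOLVER_RTOL, M=M, maxiter=20 * K_ff.shape[0])
    if info != 0:
        raise SolverError(f"conjugate gradient failed to converge (info={info})")
    return x


def apply_dirichlet(
    K: sp.csr_array, fixed_idx: np.ndarray, fixed_vals: np.ndarray
) -> tuple[sp.csr_array, np.ndarray, np.ndarray]:
    """Eliminate Dirichlet dofs; returns (K_ff, rhs_correction, free_idx)."""
    n = K.shape[0]
    free = np.setdiff1d(np.arange(n), fixed_idx)
    K_csc = K.tocsc()
    K_ff = K_csc[free][:, free].tocsr()
    K_fc = K_csc[free][:, fixed_idx]
    rhs = -K_fc @ fixed_vals
    return K_ff, rhs, free


def solve_steady_state(
    mesh: TetMesh, seeds: SeedSet, props: ThermalProps | None = None
) -> np.ndarray:
    """Solve the steady-state conduction problem for the nodal temperature field.

    Seed nodes are held at their prescribed values (exactly); every other
    boundary face is insulated.  Raises :class:`SolverError` when a connected
    component of the mesh carries no seed (its temperature would be
    undefined).
    """
    seeds = seeds.expand_patches(mesh)
    if seeds.node_ids.max() >= mesh.n_nodes:
        raise ValueError("seed node index outside mesh")
    K = assemble_conduction_system(mesh, props)
    # every connected component needs at least one seed
    n_comp, comp = csgraph.connected_components(K, directed=False)
    if n_comp > 1:
        seeded = set(comp[seeds.node_ids])
        missing = sorted(set(range(n_comp)) - seeded)
        if missing:
            raise SolverError(
                f"mesh has {n_comp} connected components; component(s) {missing} "
                "contain no seed node — their temperature is undefined"
            )
    T = np.empty(mesh.n_nodes)
    T[seeds.node_ids] = seeds.temperatures
    K_ff, rhs, free = apply_dirichlet(K, seeds.node_ids, seeds.temperatures)
    T[free] = _solve_spd(K_ff, rhs, mesh.n_nodes)
    return T


def check_bounds(field: np.ndarray, seeds: SeedSet, rel_tol: float = 1e-9) -> dict:
    """Discrete-maximum-principle diagnostic.

    Reports nodes whose value leaves the seed range by more than
    ``rel_tol * (seed range)``.  A harmonic field on a mesh whose conduction
    matrix is an M-matrix (e.g. acute structured meshes) has no violations;
    obtuse tets can produce small legitimate over/undershoots.
    """
    lo, hi = seeds.value_range
    span = max(hi - lo, abs(hi), 1e-300)
    tol = rel_tol * span
    below = np.nonzero(field < lo - tol)[0]
    above = np.nonzero(field > hi + tol)[0]
    violations = [(int(i), float(field[i])) for i in np.concatenate([below, above])]
    return {
        "min": float(field.min()),
        "max": float(field.max()),
        "seed_min": lo,
        "seed_max": hi,
        "violations": violations,
    }


def read_seeds_csv(path: str | Path, mesh: TetMesh, patch_radius: float = 0.0) -> SeedSet:
    """Read seeds from CSV: columns either (node_id, value) or (x, y, z, value).

    Coordinate rows are snapped to the nearest mesh node.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "node_id" in cols:
        ids = df[cols["node_id"]].to_numpy(dtype=np.intp)
    elif {"x", "y", "z"} <= cols.keys():
        pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        ids = np.array([mesh.locate_nearest_node(p) for p in pts], dtype=np.intp)
    else:
        raise ValueError(
            f"{path}: seed CSV needs either a 'node_id' column or 'x','y','z' columns"
        )
    value_col = next(
        (cols[c] for c in ("value", "temperature", "t") if c in cols), None
    )
    if value_col is None:
        raise ValueError(f"{path}: seed CSV needs a 'value' (or 'temperature') column")
    return SeedSet(ids, df[value_col].to_numpy(dtype=float), patch_radius=patch_radius)
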