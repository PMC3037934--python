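"""Strain tensors, principal strains, maximum shear strain, probe reports.

Strain is the comparison currency of cranial FE validation: in vivo rosette
gauges report maximum shear strain and principal values at discrete sites,
and material models are judged by how well the model reproduces them at
matching locations.

Conventions (stated because the literature is loose about them):

* tensors are stored with *tensor* shear components (eps_xy = gamma_xy / 2);
* principal strains sorted descending, eps1 >= eps2 >= eps3;
* maximum shear strain is the *engineering* value gamma_max = eps1 - eps3
  — twice the tensor maximum shear — which is the quantity a strain-gauge
  rosette analysis reports;
* probe outputs are in microstrain (×10⁶).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import ProbeSet, TetMesh, find_containing_tet
from .elasticity import element_b_matrices

MICRO = 1e6


@dataclass
class StrainState:
    """Per-element constant small-strain tensors with principal decomposition."""

    tensors: np.ndarray      # (n_tets, 3, 3), symmetric, tensor shear
    principals: np.ndarray   # (n_tets, 3), sorted descending
    directions: np.ndarray   # (n_tets, 3, 3), directions[:, :, i] pairs with principals[:, i]

    @property
    def n_elements(self) -> int:
        return len(self.tensors)

    @property
    def max_shear(self) -> np.ndarray:
        """Engineering maximum shear strain eps1 - eps3 (dimensionless)."""
        return self.principals[:, 0] - self.principals[:, 2]

    @property
    def principal_ratio(self) -> np.ndarray:
        """|eps1 / eps3|, with 0/0 reported as nan."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.abs(self.principals[:, 0] / self.principals[:, 2])

    @classmethod
    def from_tensors(cls, tensors: np.ndarray) -> "StrainState":
        tensors = np.asarray(tensors, dtype=float)
        sym = 0.5 * (tensors + np.swapaxes(tensors, 1, 2))
        vals, vecs = np.linalg.eigh(sym)  # ascending
        vals = vals[:, ::-1]
        vecs = vecs[:, :, ::-1]
        return cls(tensors=sym, principals=vals, directions=vecs)


def element_strain(mesh: TetMesh, displacements: np.ndarray) -> StrainState:
    """Constant strain of every element: eps = sym(grad u) via the B matrix."""
    u = np.asarray(displacements, dtype=float).reshape(mesh.n_nodes, 3)
    B, _ = element_b_matrices(mesh)
    ue = u[mesh.tets].reshape(mesh.n_tets, 12)
    voigt = np.einsum("eij,ej->ei", B, ue)  # engineering shear rows
    t = np.zeros((mesh.n_tets, 3, 3))
    t[:, 0, 0] = voigt[:, 0]
    t[:, 1, 1] = voigt[:, 1]
    t[:, 2, 2] = voigt[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = 0.5 * voigt[:, 3]
    t[:, 1, 2] = t[:, 2, 1] = 0.5 * voigt[:, 4]
    t[:, 0, 2] = t[:, 2, 0] = 0.5 * voigt[:, 5]
    return StrainState.from_tensors(t)


def max_shear_strain(state: StrainState, microstrain: bool = True) -> np.ndarray:
    """gamma_max = eps1 - eps3 per element, in microstrain by default."""
    g = state.max_shear
    return g * MICRO if microstrain else g


def _principal_angles(direction: np.ndarray) -> tuple[float, float, float]:
    """Direction angles (degrees, in [0, 90]) of a principal axis vs x, y, z."""
    d = direction / np.linalg.norm(direction)
    return tuple(float(np.degrees(np.arccos(min(1.0, abs(c))))) for c in d)


def probe_strains(
    mesh: TetMesh,
    state: StrainState,
    probes: ProbeSet,
    mode: str = "containing_element",
) -> pd.DataFrame:
    """Report strain quantities at probe points.

    ``containing_element``: each probe takes the (constant) tensor of the tet
    containing it — error if the point lies outside the mesh.
    ``nodal_average``: the probe snaps to the nearest node and takes the
    volume-weighted average of the tensors of the elements sharing that
    node, eigendecomposed after averaging; the snap distance is reported.

    Returns a DataFrame indexed by probe label with columns eps1_micro,
    eps3_micro, gamma_max_micro, ratio, and principal-direction angles.
    """
    if mode not in ("containing_element", "nodal_average"):
        raise ValueError(f"unknown probe mode {mode!r}")
    rows = []
    vols = mesh.volumes()
    for label, point in zip(probes.labels, probes.points):
        snap = 0.0
        if mode == "containing_element":
            e = find_containing_tet(mesh, point)
            if e < 0:
                raise ValueError(
                    f"probe {label!r} at {tuple(point)} lies outside every element"
                )
            tensor = state.tensors[e]
        else:
            nid = mesh.locate_nearest_node(point)
            snap = float(np.linalg.norm(mesh.node_coords[nid] - point))
            adj = np.nonzero(np.any(mesh.tets == nid, axis=1))[0]
            w = vols[adj]
            tensor = np.einsum("e,eij->ij", w, state.tensors[adj]) / w.sum()
        single = StrainState.from_tensors(tensor[None])
        e1, _, e3 = single.principals[0]
        ax, ay, az = _principal_angles(single.directions[0][:, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = abs(e1 / e3) if e3 != 0 else np.nan
        rows.append(
            {
                "label": label,
                "eps1_micro": e1 * MICRO,
                "eps3_micro": e3 * MICRO,
                "gamma_max_micro": (e1 - e3) * MICRO,
                "ratio": ratio,
                "dir1_angle_x_deg": ax,
                "dir1_angle_y_deg": ay,
                "dir1_angle_z_deg": az,
                "snap_distance_m": snap,
            }
        )
    return pd.DataFrame(rows).set_index("label")


def compare_modes(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Side-by-side per-probe gamma_max for several material-mode runs.

    ``reports`` maps mode name → probe report (same probe labels).  Output
    has one gamma_max column per mode plus pairwise relative differences
    (|a − b| / max(|a|, |b|)).
    """
    names = list(reports)
    if len(names) < 2:
        raise ValueError("need at least two runs to compare")
    base = reports[names[0]].index
    for name in names[1:]:
        if not base.equals(reports[name].index):
            raise ValueError(
                f"probe labels of run {name!r} do not match run {names[0]!r}"
            )
    out = pd.DataFrame(
        {f"gamma_max_{n}": reports[n]["gamma_max_micro"] for n in names}, index=base
    )
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga, gb = out[f"gamma_max_{a}"], out[f"gamma_max_{b}"]
            denom = np.maximum(np.abs(ga), np.abs(gb))
            out[f"rel_diff_{a}_vs_{b}"] = np.abs(ga - gb) / denom.replace(0.0, np.nan)
    return out


def read_probes_csv(path: str | Path) -> ProbeSet:
    """Probe CSV with columns (label, x, y, z)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    missing = {"label", "x", "y", "z"} - cols.keys()
    if missing:
        raise ValueError(f"{path}: probe CSV missing columns {sorted(missing)}")
    return ProbeSet(
        labels=[str(v) for v in df[cols["label"]]],
        points=df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float),
    )


def write_probe_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, float_format="%.10g")
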