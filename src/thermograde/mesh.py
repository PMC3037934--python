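"""Tetrahedral mesh data model and geometric queries.

The single geometric substrate shared by the thermal and structural solves:
nodes in meters, 4-node linear tetrahedra, one region label per tet, and the
list of boundary faces.  Indexing is 0-based internally; file dialects that
count from 1 are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Raised for invalid or unsupported mesh content."""


@dataclass
class TetMesh:
    """Linear tetrahedral volume mesh with per-element region labels.

    Parameters
    ----------
    node_coords : (n_nodes, 3) float array
        Node positions in meters.
    tets : (n_tets, 4) int array
        Node indices of each tetrahedron.  On validation the ordering is
        corrected (two nodes swapped) so every signed volume is positive.
    region_of_tet : (n_tets,) array of str
        Region label of each tetrahedron.  A single label ``"default"`` is
        used when a file carries no region information.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    region_of_tet: np.ndarray = None  # type: ignore[assignment]
    _boundary_faces: np.ndarray | None = field(default=None, repr=False)
    _boundary_owner: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_coords = np.ascontiguousarray(self.node_coords, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.intp)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise MeshError("node_coords must be (n_nodes, 3)")
        if self.tets.size == 0:
            raise MeshError("mesh contains no tetrahedra")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshError("tets must be (n_tets, 4); only 4-node tetrahedra are supported")
        if self.region_of_tet is None:
            self.region_of_tet = np.full(len(self.tets), "default", dtype=object)
        self.region_of_tet = np.asarray(self.region_of_tet, dtype=object)
        if len(self.region_of_tet) != len(self.tets):
            raise MeshError("region_of_tet length must equal number of tets")
        self._validate_and_orient()

    # -- validation -----------------------------------------------------

    def _validate_and_orient(self) -> None:
        n = len(self.node_coords)
        if self.tets.min() < 0 or self.tets.max() >= n:
            raise MeshError("tet references a node index outside the mesh")
        # no repeated node within a tet
        sorted_tets = np.sort(self.tets, axis=1)
        if np.any(sorted_tets[:, :-1] == sorted_tets[:, 1:]):
            bad = int(np.nonzero(np.any(sorted_tets[:, :-1] == sorted_tets[:, 1:], axis=1))[0][0])
            raise MeshError(f"degenerate tet {bad}: repeated node index")
        vols = self.signed_volumes()
        flip = vols < 0
        if np.any(flip):
            self.tets = self.tets.copy()
            self.tets[flip, 1], self.tets[flip, 2] = (
                self.tets[flip, 2].copy(),
                self.tets[flip, 1].copy(),
            )
            vols = self.signed_volumes()
        if np.any(vols <= 0):
            bad = int(np.nonzero(vols <= 0)[0][0])
            raise MeshError(f"tet {bad} has zero volume (degenerate geometry)")

    # -- basic queries --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def region_labels(self) -> list[str]:
        """Sorted list of distinct region labels."""
        return sorted({str(r) for r in self.region_of_tet})

    def signed_volumes(self) -> np.ndarray:
        """Signed volume of every tet: det of the edge matrix over six."""
        x = self.node_coords[self.tets]  # (n, 4, 3)
        d = x[:, 1:] - x[:, :1]  # (n, 3, 3) edge vectors from node 0
        return np.linalg.det(d) / 6.0

    def volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def tet_volume(self, tet_index: int) -> float:
        """Volume (m^3) of one tetrahedron; one sixth of the edge triple product."""
        x = self.node_coords[self.tets[tet_index]]
        d = x[1:] - x[0]
        return abs(float(np.linalg.det(d))) / 6.0

    def centroids(self) -> np.ndarray:
        return self.node_coords[self.tets].mean(axis=1)

    def locate_nearest_node(self, point) -> int:
        """Index of the node closest to ``point``; ties go to the lowest index."""
        p = np.asarray(point, dtype=float)
        d2 = np.einsum("ij,ij->i", self.node_coords - p, self.node_coords - p)
        return int(np.argmin(d2))  # argmin returns the first (lowest) index on ties

    def shape_gradients(self) -> tuple[np.ndarray, np.ndarray]:
        """Gradients of the four linear shape functions of every tet.

        Returns
        -------
        grads : (n_tets, 4, 3) array
            Constant gradient of each barycentric shape function.
        vols : (n_tets,) array
            Element volumes.
        """
        x = self.node_coords[self.tets]
        d = x[:, 1:] - x[:, :1]  # (n, 3, 3): rows are edge vectors e1, e2, e3
        vols = np.linalg.det(d) / 6.0
        dinv = np.linalg.inv(d)  # columns of dinv are grad(lambda_1..3)
        grads = np.empty((len(self.tets), 4, 3))
        grads[:, 1:, :] = np.swapaxes(dinv, 1, 2)
        grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
        return grads, vols

    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """Faces that belong to exactly one tet, with the owning tet index.

        Returns ``(faces, owners)`` where ``faces`` is (n_bf, 3) node indices
        and ``owners`` the owning tet of each face.
        """
        if self._boundary_faces is None:
            face_local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
            faces = self.tets[:, face_local].reshape(-1, 3)
            owners = np.repeat(np.arange(self.n_tets), 4)
            key = np.sort(faces, axis=1)
            order = np.lexsort(key.T[::-1])
            key_sorted = key[order]
            uniq, first, counts = np.unique(
                key_sorted, axis=0, return_index=True, return_counts=True
            )
            single = first[counts == 1]
            sel = order[single]
            self._boundary_faces = faces[sel]
            self._boundary_owner = owners[sel]
        return self._boundary_faces, self._boundary_owner

    def boundary_nodes(self) -> np.ndarray:
        faces, _ = self.boundary_faces()
        return np.unique(faces)

    def nodes_on_plane(self, axis: int, value: float, tol: float = 1e-9) -> np.ndarray:
        """Indices of nodes whose ``axis`` coordinate equals ``value`` within tol."""
        return np.nonzero(np.abs(self.node_coords[:, axis] - value) <= tol)[0]


@dataclass
class ProbeSet:
    """Labelled probe points at which strain quantities are reported."""

    labels: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.labels) != len(self.points):
            raise ValueError("one label per probe point required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("probe labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)


def find_containing_tet(mesh: TetMesh, point, tol: float = 1e-9) -> int:
    """Index of a tet containing ``point`` (barycentric test), or -1."""
    p = np.asarray(point, dtype=float)
    x = mesh.node_coords[mesh.tets]
    d = x[:, 1:] - x[:, :1]
    rhs = p[None, :] - x[:, 0, :]
    lam = np.linalg.solve(np.swapaxes(d, 1, 2), rhs[:, :, None])[:, :, 0]
    bary = np.column_stack([1.0 - lam.sum(axis=1), lam])
    inside = np.all(bary >= -tol, axis=1)
    idx = np.nonzero(inside)[0]
    return int(idx[0]) if len(idx) else -1
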