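"""Readers and writers for tetrahedral meshes and nodal/element fields.

Supported dialects (ASCII only):

* Gmsh ``.msh`` MSH2 and MSH4.1, 4-node tetrahedra (element type 4), region
  labels from physical groups (``$PhysicalNames`` when present).
* VTK legacy ``.vtk`` unstructured grids (cell type 10).
* VTK XML ``.vtu`` unstructured grids; point/cell data round-trips.  Region
  labels are written as an integer ``region_id`` cell array plus an XML
  comment carrying the id → name table.
* Abaqus ``.inp``: ``*NODE`` / ``*ELEMENT, TYPE=C3D4`` with ``*ELSET``
  blocks as regions.

Anything that is not a linear tetrahedron is rejected loudly: the element
formulation downstream (constant-gradient linear shape functions) is only
valid for this element.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import MeshError, TetMesh

#: Gmsh element type -> human name, for error messages
_GMSH_TYPE_NAMES = {
    1: "2-node line", 2: "3-node triangle", 3: "4-node quadrangle",
    4: "4-node tetrahedron", 5: "8-node hexahedron", 6: "6-node prism",
    7: "5-node pyramid", 11: "10-node tetrahedron", 15: "1-node point",
}
_VTK_TYPE_NAMES = {
    3: "line", 5: "triangle", 9: "quad", 10: "tetra", 12: "hexahedron",
    13: "wedge", 14: "pyramid", 24: "quadratic tetra",
}


def read_mesh(path: str | Path, format: str = "auto") -> TetMesh:
    """Read a tetrahedral volume mesh.

    Parameters
    ----------
    path : path to the mesh file
    format : one of ``{"gmsh", "vtk", "vtu", "abaqus-inp", "auto"}``;
        ``auto`` dispatches on the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = {
            ".msh": "gmsh", ".vtk": "vtk", ".vtu": "vtu", ".inp": "abaqus-inp",
        }.get(path.suffix.lower(), "")
        if not format:
            raise MeshError(f"cannot infer mesh format from extension {path.suffix!r}")
    readers = {
        "gmsh": _read_gmsh, "vtk": _read_vtk_legacy,
        "vtu": _read_vtu, "abaqus-inp": _read_abaqus,
    }
    if format not in readers:
        raise MeshError(f"unsupported mesh format {format!r}")
    return readers[format](path)


# ---------------------------------------------------------------- Gmsh

def _read_gmsh(path: Path) -> TetMesh:
    text = path.read_text()
    m = re.search(r"\$MeshFormat\s+([\d.]+)", text)
    if not m:
        raise MeshError(f"{path}: not a Gmsh file (no $MeshFormat)")
    version = float(m.group(1))
    phys_names = _gmsh_physical_names(text)
    if version >= 4:
        return _read_gmsh4(text, phys_names, path)
    return _read_gmsh2(text, phys_names, path)


def _gmsh_section(text: str, name: str) -> str | None:
    m = re.search(rf"\${name}\n(.*?)\$End{name}", text, re.S)
    return m.group(1) if m else None


def _gmsh_physical_names(text: str) -> dict[int, str]:
    sec = _gmsh_section(text, "PhysicalNames")
    names: dict[int, str] = {}
    if sec:
        lines = sec.strip().splitlines()
        for line in lines[1:]:
            parts = line.split(maxsplit=2)
            if len(parts) == 3:
                names[int(parts[1])] = parts[2].strip().strip('"')
    return names


def _read_gmsh2(text: str, phys_names: dict[int, str], path: Path) -> TetMesh:
    nodes_sec = _gmsh_section(text, "Nodes")
    elems_sec = _gmsh_section(text, "Elements")
    if nodes_sec is None or elems_sec is None:
        raise MeshError(f"{path}: missing $Nodes or $Elements section")
    node_lines = nodes_sec.strip().splitlines()
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.intp)
    coords = np.empty((n_nodes, 3))
    for i, line in enumerate(node_lines[1 : 1 + n_nodes]):
        parts = line.split()
        ids[i] = int(parts[0])
        coords[i] = [float(v) for v in parts[1:4]]
    id_to_idx = {int(t): i for i, t in enumerate(ids)}

    elem_lines = elems_sec.strip().splitlines()
    n_elems = int(elem_lines[0])
    tets, regions = [], []
    for line in elem_lines[1 : 1 + n_elems]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        conn = parts[3 + ntags :]
        if etype == 4:
            tets.append([id_to_idx[c] for c in conn])
            phys = parts[3] if ntags >= 1 else 0
            regions.append(phys_names.get(phys, str(phys) if phys else "default"))
        elif etype in (1, 2, 3, 15):
            continue  # lower-dimensional entities are legal but ignored
        else:
            name = _GMSH_TYPE_NAMES.get(etype, f"type {etype}")
            raise MeshError(f"{path}: unsupported element type: {name}; only 4-node tetrahedra are supported")
    if not tets:
        raise MeshError(f"{path}: mesh contains no tetrahedra")
    return TetMesh(coords, np.array(tets), np.array(regions, dtype=object))


def _read_gmsh4(text: str, phys_names: dict[int, str], path: Path) -> TetMesh:
    nodes_sec = _gmsh_section(text, "Nodes")
    elems_sec = _gmsh_section(text, "Elements")
    if nodes_sec is None or elems_sec is None:
        raise MeshError(f"{path}: missing $Nodes or $Elements section")
    # map volume entity tag -> physical tag (for region labels)
    ent_phys: dict[int, int] = {}
    ent_sec = _gmsh_section(text, "Entities")
    if ent_sec:
        try:
            tok = ent_sec.split()
            np_, nc, ns, nv = (int(t) for t in tok[:4])
            i = 4
            for _ in range(np_):  # points: tag, x, y, z, numPhys, phys...
                i += 4
                nphys = int(tok[i]); i += 1 + nphys
            # curves/surfaces/volumes: tag + 6 bbox + nPhys + phys + nBound + bound
            for count, store in ((nc, False), (ns, False), (nv, True)):
                for _ in range(count):
                    tag = int(tok[i]); i += 7
                    nphys = int(tok[i]); i += 1
                    phys = [int(tok[i + j]) for j in range(nphys)]; i += nphys
                    nb = int(tok[i]); i += 1 + nb
                    if store and phys:
                        ent_phys[tag] = phys[0]
        except (ValueError, IndexError):
            ent_phys = {}  # malformed entity block: fall back to unlabelled regions

    tok = nodes_sec.split()
    n_blocks = int(tok[0])
    i = 4
    ids: list[int] = []
    coords: list[list[float]] = []
    for _ in range(n_blocks):
        n_in_block = int(tok[i + 3])
        i += 4
        blk_ids = [int(tok[i + j]) for j in range(n_in_block)]
        i += n_in_block
        for j in range(n_in_block):
            coords.append([float(tok[i + 3 * j + a]) for a in range(3)])
        i += 3 * n_in_block
        ids.extend(blk_ids)
    id_to_idx = {t: k for k, t in enumerate(ids)}
    coords_arr = np.array(coords)

    tok = elems_sec.split()
    n_blocks = int(tok[0])
    i = 4
    tets, regions = [], []
    for _ in range(n_blocks):
        ent_dim, ent_tag, etype, n_in_block = (int(tok[i + k]) for k in range(4))
        i += 4
        n_per = {1: 3, 2: 4, 3: 5, 4: 5, 15: 2}.get(etype)
        if n_per is None:
            name = _GMSH_TYPE_NAMES.get(etype, f"type {etype}")
            raise MeshError(f"{path}: unsupported element type: {name}; only 4-node tetrahedra are supported")
        for _ in range(n_in_block):
            row = tok[i : i + n_per]
            i += n_per
            if etype == 4:
                tets.append([id_to_idx[int(c)] for c in row[1:]])
                phys = ent_phys.get(ent_tag, 0)
                regions.append(phys_names.get(phys, str(phys) if phys else "default"))
    if not tets:
        raise MeshError(f"{path}: mesh contains no tetrahedra")
    return TetMesh(coords_arr, np.array(tets), np.array(regions, dtype=object))


def write_gmsh2(mesh: TetMesh, path: str | Path) -> None:
    """Write a mesh as Gmsh MSH2 ASCII with physical names as regions."""
    labels = mesh.region_labels
    label_id = {lab: i + 1 for i, lab in enumerate(labels)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(labels))]
    lines += [f'3 {label_id[lab]} "{lab}"' for lab in labels]
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    lines += [
        f"{i + 1} {x:.17g} {y:.17g} {z:.17g}"
        for i, (x, y, z) in enumerate(mesh.node_coords)
    ]
    lines += ["$EndNodes", "$Elements", str(mesh.n_tets)]
    for e, conn in enumerate(mesh.tets):
        pid = label_id[str(mesh.region_of_tet[e])]
        c = " ".join(str(v + 1) for v in conn)
        lines.append(f"{e + 1} 4 2 {pid} {pid} {c}")
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


# --------------------------------------------------------- VTK legacy

def _read_vtk_legacy(path: Path) -> TetMesh:
    tok = path.read_text().split()
    upper = [t.upper() for t in tok]
    if "UNSTRUCTURED_GRID" not in upper:
        raise MeshError(f"{path}: only legacy VTK UNSTRUCTURED_GRID is supported")
    i = upper.index("POINTS")
    n_pts = int(tok[i + 1])
    coords = np.array(tok[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i = upper.index("CELLS")
    n_cells = int(tok[i + 1])
    total = int(tok[i + 2])
    flat = np.array(tok[i + 3 : i + 3 + total], dtype=np.intp)
    j = upper.index("CELL_TYPES")
    types = np.array(tok[j + 2 : j + 2 + n_cells], dtype=int)
    tets = []
    p = 0
    for c in range(n_cells):
        cnt = int(flat[p])
        conn = flat[p + 1 : p + 1 + cnt]
        p += 1 + cnt
        if types[c] == 10:
            tets.append(conn)
        elif types[c] in (1, 3, 5):
            continue
        else:
            name = _VTK_TYPE_NAMES.get(int(types[c]), f"type {types[c]}")
            raise MeshError(f"{path}: unsupported element type: {name}; only 4-node tetrahedra are supported")
    if not tets:
        raise MeshError(f"{path}: mesh contains no tetrahedra")
    return TetMesh(coords, np.array(tets))


def write_vtk_legacy(mesh: TetMesh, path: str | Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0", "thermograde mesh", "ASCII",
        "DATASET UNSTRUCTURED_GRID", f"POINTS {mesh.n_nodes} double",
    ]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.node_coords]
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    lines += ["4 " + " ".join(str(v) for v in conn) for conn in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines += ["10"] * mesh.n_tets
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- VTU

def _vtu_data_array(parent: ET.Element, name: str, data: np.ndarray) -> None:
    data = np.asarray(data)
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    is_int = np.issubdtype(data.dtype, np.integer)
    da = ET.SubElement(
        parent, "DataArray",
        type="Int64" if is_int else "Float64",
        Name=name, NumberOfComponents=str(ncomp), format="ascii",
    )
    flat = data.reshape(-1)
    fmt = (lambda v: str(int(v))) if is_int else (lambda v: f"{v:.17g}")
    da.text = " ".join(fmt(v) for v in flat)


def write_vtu(
    mesh: TetMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and optional fields as an ASCII ``.vtu`` file.

    Point data arrays must have one entry (scalar) or one length-3 vector per
    node; cell data one entry per tet.  Region labels are stored as a
    ``region_id`` cell array; the id → name table travels in an XML comment.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    for name, arr in point_data.items():
        if len(np.asarray(arr)) != mesh.n_nodes:
            raise ValueError(f"point data {name!r}: length {len(arr)} != n_nodes {mesh.n_nodes}")
    for name, arr in cell_data.items():
        if len(np.asarray(arr)) != mesh.n_tets:
            raise ValueError(f"cell data {name!r}: length {len(arr)} != n_tets {mesh.n_tets}")

    labels = mesh.region_labels
    label_id = {lab: i for i, lab in enumerate(labels)}
    region_ids = np.array([label_id[str(r)] for r in mesh.region_of_tet], dtype=np.int64)
    cell_data.setdefault("region_id", region_ids)

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    root.append(ET.Comment(" region_labels: " + json.dumps(labels) + " "))
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(mesh.n_tets)
    )
    pts = ET.SubElement(piece, "Points")
    _vtu_data_array(pts, "Points", mesh.node_coords)
    cells = ET.SubElement(piece, "Cells")
    _vtu_data_array(cells, "connectivity", mesh.tets.astype(np.int64))
    _vtu_data_array(cells, "offsets", 4 * np.arange(1, mesh.n_tets + 1, dtype=np.int64))
    _vtu_data_array(cells, "types", np.full(mesh.n_tets, 10, dtype=np.int64))
    pd = ET.SubElement(piece, "PointData")
    for name, arr in point_data.items():
        _vtu_data_array(pd, name, np.asarray(arr, dtype=float))
    cd = ET.SubElement(piece, "CellData")
    for name, arr in cell_data.items():
        _vtu_data_array(cd, name, np.asarray(arr))
    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True, encoding="utf-8"))


def _read_vtu(path: Path):
    mesh, _, _ = read_vtu_with_data(path)
    return mesh


def read_vtu_with_data(path: str | Path):
    """Read an ASCII ``.vtu`` file; returns ``(mesh, point_data, cell_data)``."""
    path = Path(path)
    text = path.read_text()
    labels = None
    m = re.search(r"<!--\s*region_labels:\s*(\[.*?\])\s*-->", text)
    if m:
        labels = json.loads(m.group(1))
    root = ET.fromstring(text)
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshError(f"{path}: no <Piece> in VTU file")

    def parse(da: ET.Element) -> np.ndarray:
        if da.get("format", "ascii") != "ascii":
            raise MeshError(f"{path}: only ascii-format VTU is supported")
        dtype = np.int64 if da.get("type", "").startswith(("Int", "UInt")) else float
        vals = np.array((da.text or "").split(), dtype=dtype)
        ncomp = int(da.get("NumberOfComponents", "1"))
        return vals.reshape(-1, ncomp) if ncomp > 1 else vals

    coords = parse(piece.find("Points/DataArray"))
    arrays = {da.get("Name"): parse(da) for da in piece.findall("Cells/DataArray")}
    conn, offsets, types = arrays["connectivity"], arrays["offsets"], arrays["types"]
    if not np.all(types == 10):
        bad = int(types[types != 10][0])
        name = _VTK_TYPE_NAMES.get(bad, f"type {bad}")
        raise MeshError(f"{path}: unsupported element type: {name}; only 4-node tetrahedra are supported")
    starts = np.concatenate([[0], offsets[:-1]])
    if not np.all(offsets - starts == 4):
        raise MeshError(f"{path}: non-tetrahedral connectivity block")
    tets = conn.reshape(-1, 4)
    point_data = {da.get("Name"): parse(da) for da in piece.findall("PointData/DataArray")}
    cell_data = {da.get("Name"): parse(da) for da in piece.findall("CellData/DataArray")}
    regions = None
    if "region_id" in cell_data:
        rid = cell_data["region_id"].astype(int)
        if labels is not None:
            regions = np.array([labels[i] for i in rid], dtype=object)
        else:
            regions = np.array([str(i) for i in rid], dtype=object)
    mesh = TetMesh(coords, tets, regions)
    return mesh, point_data, cell_data


# -------------------------------------------------------------- Abaqus

def _read_abaqus(path: Path) -> TetMesh:
    ids: list[int] = []
    coords: list[list[float]] = []
    tets: list[list[int]] = []
    elem_ids: list[int] = []
    elsets: dict[str, list[int]] = {}
    section = None
    current_set: str | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw = line.split(",")[0].strip().upper()
            opts = {
                k.strip().upper(): v.strip()
                for k, v in (p.split("=") for p in line.split(",")[1:] if "=" in p)
            }
            if kw == "*NODE":
                section = "node"
            elif kw == "*ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype != "C3D4":
                    raise MeshError(
                        f"{path}: unsupported element type: {etype or 'unspecified'}; only C3D4 tetrahedra are supported"
                    )
                section = "element"
                current_set = opts.get("ELSET")
            elif kw == "*ELSET":
                section = "elset"
                current_set = opts.get("ELSET", "default")
                elsets.setdefault(current_set, [])
            else:
                section = None
            continue
        parts = [p.strip() for p in line.split(",") if p.strip()]
        if section == "node":
            ids.append(int(parts[0]))
            coords.append([float(v) for v in parts[1:4]])
        elif section == "element":
            eid = int(parts[0])
            elem_ids.append(eid)
            tets.append([int(v) for v in parts[1:5]])
            if current_set:
                elsets.setdefault(current_set, []).append(eid)
        elif section == "elset":
            elsets[current_set].extend(int(v) for v in parts)
    if not tets:
        raise MeshError(f"{path}: mesh contains no tetrahedra")
    id_to_idx = {t: i for i, t in enumerate(ids)}
    conn = np.array([[id_to_idx[v] for v in t] for t in tets])
    eid_to_row = {e: i for i, e in enumerate(elem_ids)}
    regions = np.full(len(tets), "default", dtype=object)
    for name, members in elsets.items():
        for eid in members:
            if eid in eid_to_row:
                regions[eid_to_row[eid]] = name
    return TetMesh(np.array(coords), conn, regions)


def write_point_field(mesh: TetMesh, field: np.ndarray, path: str | Path, name: str) -> None:
    """Write one nodal field (scalar or 3-vector per node) as VTU point data."""
    field = np.asarray(field, dtype=float)
    if len(field) != mesh.n_nodes:
        raise ValueError(f"field length {len(field)} != node count {mesh.n_nodes}")
    write_vtu(mesh, path, point_data={name: field})
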