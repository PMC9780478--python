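"""Mesh, atlas and FE-deck file IO.

Triangular surfaces: STL/PLY (via trimesh; STL triangle soup is welded
on load at trimesh's default merge tolerance, 1e-8 of scale) plus
hand-written legacy-VTK and VTU (XML, ASCII) readers/writers that also
carry hexahedral cells, since no VTK binding is a dependency. FE
export writes an Abaqus-INP dialect: C3D8 continuum hexes for
cartilage, R3D3 rigid shells for bones, one node set per attachment
site; a round-trip reader reproduces counts exactly and coordinates to
full double precision.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import trimesh

from .hexsweep import HexMesh
from .phantoms import TemplateAtlas

_VTK_TRI = 5
_VTK_HEX = 12


# ---------------------------------------------------------------------------
# generic mesh read/write
# ---------------------------------------------------------------------------


def write_mesh(mesh, path) -> None:
    """Write a trimesh surface or a :class:`HexMesh` by extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if isinstance(mesh, HexMesh):
        if ext == ".vtu":
            _write_vtu(path, mesh.nodes, mesh.hexes, _VTK_HEX,
                       cell_data={"layer": mesh.layer_of})
        elif ext == ".vtk":
            _write_legacy_vtk(path, mesh.nodes, mesh.hexes, _VTK_HEX)
        elif ext == ".stl":
            # boundary skin
            tris = _quads_to_tris(mesh.boundary_quads())
            trimesh.Trimesh(mesh.nodes, tris, process=False).export(path)
        else:
            raise ValueError(f"unsupported hex-mesh format: {path.name}")
        return
    if ext in (".stl", ".ply"):
        mesh.export(path)
    elif ext == ".vtu":
        _write_vtu(path, mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray), _VTK_TRI)
    elif ext == ".vtk":
        _write_legacy_vtk(path, mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray), _VTK_TRI)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def read_mesh(path):
    """Read STL/PLY/VTK/VTU; returns a trimesh surface or :class:`HexMesh`."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".stl", ".ply"):
        out = trimesh.load(path, force="mesh")
        return out
    if ext == ".vtu":
        nodes, cells, ctype, cell_data = _read_vtu(path)
    elif ext == ".vtk":
        nodes, cells, ctype = _read_legacy_vtk(path)
        cell_data = {}
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")
    if ctype == _VTK_TRI:
        return trimesh.Trimesh(nodes, cells, process=False)
    layer = cell_data.get("layer")
    if layer is None:
        layer = np.zeros(len(cells), dtype=np.int64)
    return HexMesh(nodes, cells, int(layer.max()) + 1, layer)


def _quads_to_tris(quads):
    q = np.asarray(quads)
    return np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]])


# ---------------------------------------------------------------------------
# VTU (XML, ASCII)
# ---------------------------------------------------------------------------


def _write_vtu(path, points, cells, cell_type, cell_data=None) -> None:
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    npts, ncell = len(points), len(cells)
    k = cells.shape[1]

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(npts),
                          NumberOfCells=str(ncell))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64",
                       NumberOfComponents="3", format="ascii")
    da.text = "\n".join(" ".join(f"{x:.17g}" for x in p) for p in points)
    cel = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cel, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = "\n".join(" ".join(str(i) for i in c) for c in cells)
    off = ET.SubElement(cel, "DataArray", type="Int64", Name="offsets",
                        format="ascii")
    off.text = " ".join(str(k * (i + 1)) for i in range(ncell))
    typ = ET.SubElement(cel, "DataArray", type="UInt8", Name="types",
                        format="ascii")
    typ.text = " ".join(str(cell_type) for _ in range(ncell))
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            d = ET.SubElement(cd, "DataArray", type="Int64", Name=name,
                              format="ascii")
            d.text = " ".join(str(int(v)) for v in np.asarray(arr).ravel())
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _read_vtu(path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts_text = piece.find("./Points/DataArray").text
    points = np.fromstring(pts_text.replace("\n", " "), sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.find("./Cells")}
    conn = np.fromstring(arrays["connectivity"].text.replace("\n", " "),
                         sep=" ").astype(np.int64)
    offsets = np.fromstring(arrays["offsets"].text.replace("\n", " "),
                            sep=" ").astype(np.int64)
    types = np.fromstring(arrays["types"].text.replace("\n", " "),
                          sep=" ").astype(int)
    if len(set(types.tolist())) != 1:
        raise ValueError("mixed-cell VTU files are not supported")
    k = offsets[0]
    cells = conn.reshape(-1, k)
    cell_data = {}
    cd = piece.find("./CellData")
    if cd is not None:
        for da in cd:
            cell_data[da.get("Name")] = np.fromstring(
                da.text.replace("\n", " "), sep=" "
            ).astype(np.int64)
    return points, cells, int(types[0]), cell_data


# ---------------------------------------------------------------------------
# legacy VTK (ASCII)
# ---------------------------------------------------------------------------


def _write_legacy_vtk(path, points, cells, cell_type) -> None:
    points = np.asarray(points, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    k = cells.shape[1]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhexcart mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(" ".join(f"{x:.17g}" for x in p) + "\n")
        fh.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        for c in cells:
            fh.write(str(k) + " " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join([str(cell_type)] * len(cells)) + "\n")


def _read_legacy_vtk(path):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    npts = int(lines[i].split()[1])
    vals = []
    j = i + 1
    while len(vals) < 3 * npts:
        vals.extend(float(x) for x in lines[j].split())
        j += 1
    points = np.asarray(vals).reshape(-1, 3)
    i = next(k for k, ln in enumerate(lines) if ln.startswith("CELLS"))
    ncell = int(lines[i].split()[1])
    cells = []
    for ln in lines[i + 1 : i + 1 + ncell]:
        parts = [int(x) for x in ln.split()]
        cells.append(parts[1 : 1 + parts[0]])
    i = next(k for k, ln in enumerate(lines) if ln.startswith("CELL_TYPES"))
    ctype = int(lines[i + 1])
    return points, np.asarray(cells, dtype=np.int64), ctype


# ---------------------------------------------------------------------------
# template atlas
# ---------------------------------------------------------------------------


def save_atlas(atlas: TemplateAtlas, surface_path, sites_path) -> None:
    write_mesh(atlas.femur_surface, surface_path)
    payload = {
        "sites": [
            {"name": n, "tissue": t, "xyz": [float(c) for c in xyz]}
            for n, t, xyz in atlas.sites
        ],
        "joint_axis_points": [
            [float(c) for c in p] for p in atlas.joint_axis_points
        ],
    }
    Path(sites_path).write_text(json.dumps(payload, indent=1))


def load_atlas(surface_path, sites_path) -> TemplateAtlas:
    surf = read_mesh(surface_path)
    payload = json.loads(Path(sites_path).read_text())
    sites = [
        (s["name"], s["tissue"], np.asarray(s["xyz"], dtype=float))
        for s in payload["sites"]
    ]
    axes = [np.asarray(p, dtype=float) for p in payload.get("joint_axis_points", [])]
    names = [n for n, _, _ in sites]
    if len(set(names)) != len(names):
        raise ValueError("atlas site names are not unique")
    return TemplateAtlas(surf, sites, axes)


# ---------------------------------------------------------------------------
# FE deck (Abaqus-INP dialect)
# ---------------------------------------------------------------------------


def export_fe_deck(meshes: dict, attachment_sites, path) -> None:
    """Write hex cartilage + rigid tri bone meshes and site node sets.

    ``meshes``: tissue name -> HexMesh (cartilage) or trimesh (bone).
    ``attachment_sites``: records as produced by
    :func:`hexcart.attach.map_attachment_sites` (may be empty).
    """
    path = Path(path)
    for name, mesh in meshes.items():
        if isinstance(mesh, HexMesh) and not mesh.is_conforming():
            raise ValueError(f"refusing to export non-conforming mesh {name!r}")
    offsets = {}
    lines = ["*HEADING", "hexcart export"]
    next_node = 1
    for name, mesh in meshes.items():
        nodes = mesh.nodes if isinstance(mesh, HexMesh) else mesh.vertices.view(np.ndarray)
        offsets[name] = next_node
        lines.append(f"*NODE, NSET=NALL-{name.upper()}")
        for k, p in enumerate(nodes):
            lines.append(
                f"{next_node + k}, {p[0]:.17g}, {p[1]:.17g}, {p[2]:.17g}"
            )
        next_node += len(nodes)
    next_elem = 1
    for name, mesh in meshes.items():
        off = offsets[name]
        if isinstance(mesh, HexMesh):
            lines.append(f"*ELEMENT, TYPE=C3D8, ELSET={name.upper()}")
            cells = mesh.hexes
        else:
            lines.append(f"*ELEMENT, TYPE=R3D3, ELSET={name.upper()}")
            cells = mesh.faces.view(np.ndarray)
        for k, c in enumerate(cells):
            ids = ", ".join(str(int(v) + off) for v in c)
            lines.append(f"{next_elem + k}, {ids}")
        next_elem += len(cells)
    for rec in attachment_sites or []:
        tissue = rec["tissue"]
        if tissue not in offsets:
            continue
        nid = offsets[tissue] + int(rec["node_id"])
        lines.append(f"*NSET, NSET={rec['name'].upper()}")
        lines.append(str(nid))
    path.write_text("\n".join(lines) + "\n")


def read_fe_deck(path):
    """Parse a deck written by :func:`export_fe_deck`."""
    nodes = {}
    elements = {}  # elset -> (type, list of node-id tuples)
    nsets = {}
    mode = None
    current = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("*"):
            key = line.split(",")[0].upper()
            opts = dict(
                kv.strip().split("=")
                for kv in line.split(",")[1:]
                if "=" in kv
            )
            opts = {k.strip().upper(): v.strip() for k, v in opts.items()}
            if key == "*NODE":
                mode = "node"
            elif key == "*ELEMENT":
                mode = "elem"
                current = opts.get("ELSET", "ALL")
                elements[current] = (opts.get("TYPE", ""), [])
            elif key == "*NSET":
                mode = "nset"
                current = opts.get("NSET", "SET")
                nsets[current] = []
            else:
                mode = None
            continue
        if mode == "node":
            parts = line.split(",")
            nodes[int(parts[0])] = tuple(float(x) for x in parts[1:4])
        elif mode == "elem":
            parts = [int(x) for x in line.split(",")]
            elements[current][1].append(tuple(parts[1:]))
        elif mode == "nset":
            nsets[current].extend(int(x) for x in line.split(","))
    return {"nodes": nodes, "elements": elements, "nsets": nsets}
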