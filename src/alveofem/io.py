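"""Mesh and result file I/O.

Writers for the two interchange formats used by the package: Gmsh MSH
(version 4.1, ASCII) and VTK unstructured-grid XML (VTU, ASCII).  Material
labels are exported as MSH physical groups / VTU cell data; named node sets
as 0/1 point-data masks.  A minimal MSH reader supports round-tripping
labelled tet10 meshes (e.g. externally supplied meshes).

Node-ordering notes: the package and VTU share the same quadratic-tetra
ordering; Gmsh permutes the last three mid-edge nodes.
"""

from __future__ import annotations

import numpy as np

from .meshdata import MATERIALS, MATERIAL_CODE, LabeledMesh

__all__ = ["write_msh", "read_msh", "write_vtu", "write_fibre_vtu"]

# package/VTK edge order -> gmsh edge order for tet10 mid nodes
_GMSH_PERM = np.array([0, 1, 2, 3, 4, 5, 6, 7, 9, 8])
# package order: corners, then mids on (0,1),(1,2),(0,2),(0,3),(1,3),(2,3)
# gmsh order:    corners, then mids on (0,1),(1,2),(0,2),(0,3),(2,3),(1,3)


def write_msh(mesh: LabeledMesh, path) -> None:
    """Write the labelled mesh as Gmsh MSH 4.1 ASCII, one 3-D entity per material."""
    present = np.unique(mesh.labels)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(present))]
    for code in present:
        lines.append(f'3 {code + 1} "{MATERIALS[code]}"')
    lines.append("$EndPhysicalNames")
    # one discrete volume entity per material, tagged with its physical group
    lines += ["$Entities", f"0 0 0 {len(present)}"]
    for code in present:
        lines.append(f"{code + 1} 0 0 0 0 0 0 1 {code + 1}")
    lines.append("$EndEntities")
    n = mesh.n_nodes
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 {present[0] + 1} 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.16g} {y:.16g} {z:.16g}" for x, y, z in mesh.nodes]
    lines.append("$EndNodes")
    total = mesh.n_elements
    lines += ["$Elements", f"{len(present)} {total} 1 {total}"]
    eid = 1
    for code in present:
        idx = np.flatnonzero(mesh.labels == code)
        lines.append(f"3 {code + 1} 11 {len(idx)}")  # type 11 = 10-node tetra
        conn = mesh.elements[idx][:, _GMSH_PERM] + 1
        for row in conn:
            lines.append(str(eid) + " " + " ".join(map(str, row)))
            eid += 1
    lines.append("$EndElements")
    # node sets as $NodeData masks (one view per set)
    for name, nodes in mesh.node_sets.items():
        mask = np.zeros(n, dtype=int)
        mask[nodes] = 1
        lines += ["$NodeData", "1", f'"nodeset:{name}"', "1", "0.0", "3", "0", "1", str(n)]
        lines += [f"{i + 1} {mask[i]}" for i in range(n)]
        lines.append("$EndNodeData")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> LabeledMesh:
    """Read a labelled tet10 mesh written by :func:`write_msh` (MSH 4.1 ASCII)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(tokens)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"malformed MSH file: missing {tag}")

    until("$Nodes")
    header = next(it).split()
    n_nodes = int(header[1])
    next(it)  # block header
    ids = [int(next(it)) for _ in range(n_nodes)]
    coords = np.array([[float(v) for v in next(it).split()] for _ in range(n_nodes)])
    order = np.argsort(ids)
    coords = coords[order]
    until("$EndNodes")
    until("$Elements")
    header = next(it).split()
    n_blocks, n_elem = int(header[0]), int(header[1])
    elements = np.empty((n_elem, 10), dtype=np.int64)
    labels = np.empty(n_elem, dtype=np.int8)
    at = 0
    for _ in range(n_blocks):
        _dim, btag, etype, count = (int(v) for v in next(it).split())
        if etype != 11:
            raise ValueError("only 10-node tetrahedra are supported")
        for _ in range(count):
            row = [int(v) for v in next(it).split()]
            elements[at] = np.array(row[1:11]) - 1
            labels[at] = btag - 1
            at += 1
    elements = elements[:, np.argsort(_GMSH_PERM)]
    mesh = LabeledMesh(nodes=coords, elements=elements, labels=labels,
                       tooth_of=np.full(n_elem, -1, dtype=np.int8))
    # recover node sets from $NodeData masks
    rest = list(it)
    i = 0
    while i < len(rest):
        if rest[i].strip() == "$NodeData":
            name = rest[i + 2].strip('"')
            n = int(rest[i + 8])
            vals = np.array([int(rest[i + 9 + k].split()[1]) for k in range(n)])
            if name.startswith("nodeset:"):
                mesh.node_sets[name[len("nodeset:"):]] = np.flatnonzero(vals)
            i += 9 + n
        else:
            i += 1
    return mesh


def write_fibre_vtu(mesh: LabeledMesh, fibres, path) -> None:
    """Write a fibre set as VTK line cells (group and area as cell data)."""
    used = np.unique(np.concatenate([fibres.bone_node, fibres.root_node]))
    remap = {n: i for i, n in enumerate(used)}
    pts = mesh.nodes[used]
    conn = np.array([[remap[a], remap[b]]
                     for a, b in zip(fibres.bone_node, fibres.root_node)])
    m = len(conn)
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             "<UnstructuredGrid>", f'<Piece NumberOfPoints="{len(pts)}" NumberOfCells="{m}">',
             "<Points>",
             '<DataArray type="Float64" Name="points" NumberOfComponents="3" format="ascii">'
             + " ".join(f"{v:.10g}" for v in pts.ravel()) + "</DataArray>",
             "</Points>", "<Cells>",
             '<DataArray type="Int64" Name="connectivity" NumberOfComponents="1" format="ascii">'
             + " ".join(map(str, conn.ravel())) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" NumberOfComponents="1" format="ascii">'
             + " ".join(map(str, range(2, 2 * m + 1, 2))) + "</DataArray>",
             '<DataArray type="Int32" Name="types" NumberOfComponents="1" format="ascii">'
             + " ".join(["3"] * m) + "</DataArray>",
             "</Cells>", "<CellData>",
             '<DataArray type="Int32" Name="group" NumberOfComponents="1" format="ascii">'
             + " ".join(map(str, fibres.group.astype(int))) + "</DataArray>",
             '<DataArray type="Float64" Name="area_mm2" NumberOfComponents="1" format="ascii">'
             + " ".join(f"{v:.10g}" for v in fibres.area) + "</DataArray>",
             "</CellData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_vtu(mesh: LabeledMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None, include_node_sets: bool = True) -> None:
    """Write the mesh (VTK quadratic tetra, type 24) with optional data arrays.

    ``point_data`` arrays are per-node scalars or (n, k) components;
    ``cell_data`` per-element.  Material labels are always included.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("material", mesh.labels.astype(np.int32))
    if include_node_sets:
        for name, nodes in mesh.node_sets.items():
            mask = np.zeros(mesh.n_nodes, dtype=np.int32)
            mask[nodes] = 1
            point_data[f"nodeset_{name}"] = mask

    def data_array(name, arr):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        typ = "Int32" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        flat = " ".join(f"{v:.10g}" if typ == "Float64" else str(int(v))
                        for v in np.ravel(arr))
        return (f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">{flat}</DataArray>')

    n, m = mesh.n_nodes, mesh.n_elements
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             "<UnstructuredGrid>", f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
             "<Points>", data_array("points", mesh.nodes), "</Points>",
             "<Cells>",
             data_array("connectivity", mesh.elements.astype(np.int64)),
             data_array("offsets", np.arange(1, m + 1, dtype=np.int64) * 10),
             data_array("types", np.full(m, 24, dtype=np.int32)),
             "</Cells>"]
    parts.append("<PointData>")
    parts += [data_array(k, v) for k, v in point_data.items()]
    parts.append("</PointData>")
    parts.append("<CellData>")
    parts += [data_array(k, v) for k, v in cell_data.items()]
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
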