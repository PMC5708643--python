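"""Labelled quadratic-tetrahedral mesh containers and topology utilities.

The package works on a single conforming mesh of 10-node tetrahedra
(straight-sided, mid-edge nodes at edge midpoints) in a mm-N-MPa unit
system.  Every element carries exactly one material label out of the five
materials of the tooth-in-socket model: cortical bone, trabecular bone,
trabecular filling (the pseudo-material occupying the pores between
trabeculae), tooth and PDL (periodontal ligament matrix).

Local tet10 node ordering (VTK convention): corners 0-3, then mid-edge
nodes on edges (0,1), (1,2), (0,2), (0,3), (1,3), (2,3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MATERIALS = ("cortical", "trabecular_bone", "trabecular_filling", "tooth", "pdl")
MATERIAL_CODE = {name: i for i, name in enumerate(MATERIALS)}

#: tet10 mid-edge node -> (corner, corner)
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

#: corner triples of the four faces, plus the local ids of their mid-edge nodes
TET_FACES = ((0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3))
TET_FACE_MIDS = ((4, 5, 6), (4, 8, 7), (5, 9, 8), (6, 9, 7))


@dataclass
class LabeledMesh:
    """A conforming tet10 mesh with per-element material labels and named node sets.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array, coordinates in mm.
    elements : (n_elem, 10) int array, tet10 connectivity.
    labels : (n_elem,) int array, codes into :data:`MATERIALS`.
    tooth_of : (n_elem,) int array, tooth index for tooth/PDL elements, -1 otherwise.
    node_sets : named node-index arrays (cut faces, base edges, crown patches,
        outer cortical surfaces).
    """

    nodes: np.ndarray
    elements: np.ndarray
    labels: np.ndarray
    tooth_of: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def label_names(self) -> np.ndarray:
        return np.asarray(MATERIALS, dtype=object)[self.labels]

    def elements_of(self, *names: str) -> np.ndarray:
        codes = [MATERIAL_CODE[n] for n in names]
        return np.flatnonzero(np.isin(self.labels, codes))

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.elements)

    def set_nodes(self, name: str) -> np.ndarray:
        try:
            return self.node_sets[name]
        except KeyError:
            raise KeyError(
                f"mesh has no node set {name!r}; available: {sorted(self.node_sets)}"
            ) from None


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of (straight-sided) tetrahedra from their corner nodes."""
    p = nodes[elements[:, :4]]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def median_edge_length(mesh: LabeledMesh) -> float:
    p = mesh.nodes[mesh.elements[:, :4]]
    e = np.linalg.norm(p[:, [0, 0, 0, 1, 1, 2]] - p[:, [1, 2, 3, 2, 3, 3]], axis=2)
    return float(np.median(e))


def _face_table(elements: np.ndarray):
    """All corner-face triples (sorted) with their (element, local face) origin."""
    n = len(elements)
    faces = np.empty((4 * n, 3), dtype=np.int64)
    owner = np.empty(4 * n, dtype=np.int64)
    local = np.empty(4 * n, dtype=np.int8)
    for fi, tri in enumerate(TET_FACES):
        faces[fi * n : (fi + 1) * n] = np.sort(elements[:, tri], axis=1)
        owner[fi * n : (fi + 1) * n] = np.arange(n)
        local[fi * n : (fi + 1) * n] = fi
    return faces, owner, local


def check_conforming(mesh: LabeledMesh) -> None:
    """Every interior face must be shared by exactly two tetrahedra.

    Raises ``ValueError`` on hanging faces (shared by 3+) which would mean a
    non-conforming mesh.
    """
    faces, _, _ = _face_table(mesh.elements)
    _, counts = np.unique(faces, axis=0, return_counts=True)
    if counts.max(initial=0) > 2:
        raise ValueError("non-conforming mesh: a face is shared by more than two tets")


def boundary_faces(mesh: LabeledMesh):
    """(element, local face) pairs of faces on the mesh boundary."""
    faces, owner, local = _face_table(mesh.elements)
    uniq, inv, counts = np.unique(faces, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    return owner[on_boundary], local[on_boundary]


def interface_faces(mesh: LabeledMesh, mat_a: str, mat_b: str):
    """Interior faces shared by an element of ``mat_a`` and one of ``mat_b``.

    Returns ``(elems_a, local_a, elems_b)``: the face identified from the
    ``mat_a`` side, plus the adjacent ``mat_b`` element.
    """
    faces, owner, local = _face_table(mesh.elements)
    order = np.lexsort(faces.T)
    faces, owner, local = faces[order], owner[order], local[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    i = np.flatnonzero(same)  # faces[i] == faces[i+1]: an interior face pair
    la, lb = mesh.labels[owner[i]], mesh.labels[owner[i + 1]]
    ca, cb = MATERIAL_CODE[mat_a], MATERIAL_CODE[mat_b]
    ab = (la == ca) & (lb == cb)
    ba = (la == cb) & (lb == ca)
    elems_a = np.concatenate([owner[i[ab]], owner[i[ba] + 1]])
    local_a = np.concatenate([local[i[ab]], local[i[ba] + 1]])
    elems_b = np.concatenate([owner[i[ab] + 1], owner[i[ba]]])
    return elems_a, local_a, elems_b


@dataclass
class ToothInterface:
    """Interface node data for one tooth socket.

    ``bone_*`` arrays describe the alveolar-bone side of the PDL layer,
    ``root_*`` the tooth-root side.  Normals are unit vectors pointing from
    the owning material into the PDL; tributary areas (mm^2) partition the
    interface surface area among its nodes.
    """

    bone_nodes: np.ndarray
    bone_areas: np.ndarray
    bone_normals: np.ndarray
    root_nodes: np.ndarray
    root_areas: np.ndarray
    root_normals: np.ndarray
    apex: np.ndarray           # (3,) location of the deepest root-side node
    axis: np.ndarray           # unit vector pointing crest -> apex


@dataclass
class InterfaceSets:
    teeth: list[ToothInterface]

    def __getitem__(self, i: int) -> ToothInterface:
        return self.teeth[i]

    def __len__(self) -> int:
        return len(self.teeth)


# tributary-area weights for a 6-node triangular facet: corners get 1/12 of
# the facet area each, mid-edge nodes 1/4 each (they carry most of the area
# of a quadratic triangle; the split is a partition of unity).
_CORNER_W = 1.0 / 12.0
_MID_W = 1.0 / 4.0


def _interface_side(mesh: LabeledMesh, own_mat: str, other_mat: str, tooth: int):
    elems, locals_, neigh = interface_faces(mesh, own_mat, other_mat)
    # keep facets whose PDL-side element belongs to this tooth
    pdl_elem = neigh if other_mat == "pdl" else elems
    keep = mesh.tooth_of[pdl_elem] == tooth
    elems, locals_ = elems[keep], locals_[keep]
    if len(elems) == 0:
        return None
    conn = mesh.elements[elems]
    n_nodes = mesh.n_nodes
    areas = np.zeros(n_nodes)
    normals = np.zeros((n_nodes, 3))
    for fi in range(4):
        sel = locals_ == fi
        if not sel.any():
            continue
        tri = conn[sel][:, TET_FACES[fi]]
        mids = conn[sel][:, TET_FACE_MIDS[fi]]
        p = mesh.nodes[tri]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        a2 = np.linalg.norm(cross, axis=1)
        nrm = cross / a2[:, None]
        # orient from the owning element into the facet (toward the PDL)
        cent_f = p.mean(axis=1)
        cent_e = mesh.nodes[conn[sel][:, :4]].mean(axis=1)
        flip = np.einsum("ij,ij->i", nrm, cent_f - cent_e) < 0
        nrm[flip] *= -1.0
        area = a2 / 2.0
        for k in range(3):
            np.add.at(areas, tri[:, k], _CORNER_W * area)
            np.add.at(areas, mids[:, k], _MID_W * area)
            np.add.at(normals, tri[:, k], _CORNER_W * area[:, None] * nrm)
            np.add.at(normals, mids[:, k], _MID_W * area[:, None] * nrm)
    nodes = np.flatnonzero(areas > 0)
    nrm = normals[nodes]
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return nodes, areas[nodes], nrm


def tag_interfaces(mesh: LabeledMesh) -> InterfaceSets:
    """Identify the bone-PDL and root-PDL interface node sets of every tooth.

    Bone-side nodes are those shared by a PDL element and a cortical
    (alveolar) element; root-side nodes are shared by a PDL element and a
    tooth element.  Each node receives a tributary area and an
    area-averaged unit normal pointing into the PDL.
    """
    if not len(mesh.elements_of("pdl")):
        raise ValueError("mesh has no PDL elements; cannot tag interfaces")
    teeth_ids = np.unique(mesh.tooth_of[mesh.elements_of("pdl")])
    teeth = []
    for tooth in teeth_ids:
        bone = _interface_side(mesh, "cortical", "pdl", tooth)
        root = _interface_side(mesh, "tooth", "pdl", tooth)
        if bone is None or root is None:
            raise ValueError(f"tooth {tooth}: empty bone- or root-side PDL interface")
        r_nodes, r_areas, r_normals = root
        pts = mesh.nodes[r_nodes]
        lowest = pts[:, 2] <= pts[:, 2].min() + 1e-9
        centre_xy = pts[:, :2].mean(axis=0)
        cand = pts[lowest]
        apex = cand[np.argmin(np.linalg.norm(cand[:, :2] - centre_xy, axis=1))]
        axis = apex - pts.mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        teeth.append(
            ToothInterface(
                bone_nodes=bone[0], bone_areas=bone[1], bone_normals=bone[2],
                root_nodes=r_nodes, root_areas=r_areas, root_normals=r_normals,
                apex=apex, axis=axis,
            )
        )
    return InterfaceSets(teeth)
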