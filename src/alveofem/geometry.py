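"""Procedural tooth-in-socket geometry.

Generates labelled, conforming tet10 meshes of a block of mandibular corpus
with a cortical shell, an interior trabecular region (explicit strut/plate
lattice or homogeneous fill), one to three teeth with tapered roots seated
in sockets, and a thin periodontal-ligament (PDL) layer joining each root
to the alveolar bone.

Coordinate convention (anatomical): x = buccolingual (buccal positive),
y = mesiodistal (distal positive), z = corono-apical (coronal positive,
z = 0 at the inferior border of the corpus).  Units are mm.

Construction: a structured hex grid is generated over the corpus; around
each tooth root a local radial remapping pulls two grid "rings" exactly
onto the root surface and onto the root surface offset by the PDL
thickness, so the tooth/PDL and PDL/bone interfaces coincide with element
faces and the PDL is a one-element-thick shell of exact nominal thickness
(faceting of the circular interface introduces only a few-percent local
variation).  Each hex is split into six tetrahedra (Kuhn subdivision,
conforming across hexes) and promoted to 10-node tetrahedra with mid-edge
nodes at edge midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .meshdata import (
    MATERIAL_CODE,
    LabeledMesh,
    TET10_EDGES,
    tet_volumes,
)

__all__ = [
    "GeometryParams",
    "build_socket_geometry",
    "build_block",
    "generate_trabecular_lattice",
    "analytic_volume",
]


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic molar-region geometry (lengths in mm).

    Defaults describe a desk-scale but anatomically plausible single first
    molar seated in a block of mandibular corpus.  The PDL thickness default
    of 0.25 mm is the typical anatomical value; corpus and root dimensions
    are plausible choices, not measured ones.
    """

    corpus_width: float = 12.0        # buccolingual (x)
    corpus_length: float | None = None  # mesiodistal (y); default n_teeth * tooth_pitch
    corpus_height: float = 30.0       # inferior border to alveolar crest (z)
    cortical_thickness: float = 3.0   # two quadratic elements through the shell
    n_teeth: int = 1
    tooth_pitch: float = 12.0
    root_length: float = 12.0
    root_radius_crest: float = 3.0
    root_radius_apex: float = 1.2
    socket_wall_extent: float | None = None  # half-width of the dense socket wall ring
    root_aspect: float = 1.0          # mesiodistal/buccolingual semi-axis ratio
    two_rooted: bool = False
    root_separation: float = 6.0      # centre distance of the two roots (two-rooted)
    pdl_thickness: float = 0.25
    crown_height: float = 4.5
    trabecular_mode: str = "structure"  # "structure" | "bulk"
    lattice_spacing: float = 3.0
    lattice_porosity: float = 0.5     # pore (filling) volume fraction
    seed: int = 1
    element_size: float = 1.5
    patch_radius: float = 1.0         # load / contact patch radius on the crown
    base_patch_halfwidth: float = 2.0  # half-width (x) of each fixed base patch
    base_patch_depth: float = 1.5     # extent (y) of each base patch into the block

    @property
    def length(self) -> float:
        return self.corpus_length if self.corpus_length is not None else self.n_teeth * self.tooth_pitch

    def validate(self) -> None:
        positive = [
            "corpus_width", "corpus_height", "cortical_thickness", "tooth_pitch",
            "root_length", "root_radius_crest", "root_radius_apex", "pdl_thickness",
            "crown_height", "lattice_spacing", "element_size", "patch_radius",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"GeometryParams.{name} must be > 0")
        if not 1 <= self.n_teeth <= 3:
            raise ValueError("n_teeth must be 1, 2 or 3")
        if self.pdl_thickness >= self.root_radius_apex:
            raise ValueError("pdl_thickness must be smaller than the apical root radius")
        if not 0.0 <= self.lattice_porosity < 1.0:
            raise ValueError("lattice_porosity must lie in [0, 1)")
        if self.trabecular_mode not in ("structure", "bulk"):
            raise ValueError("trabecular_mode must be 'structure' or 'bulk'")
        if self.corpus_height <= self.root_length + self.pdl_thickness:
            raise ValueError("corpus_height must exceed root_length + pdl_thickness")
        if self.lattice_spacing < self.element_size:
            raise ValueError("lattice_spacing must be at least the element size")


# ---------------------------------------------------------------------------
# ring layout


@dataclass(frozen=True)
class _Root:
    """One root's ring layout: centre grid indices and ring radii in cells."""

    tooth: int
    ix: float
    iy: float
    c1: int
    c2: int
    c3: int
    ax_crest: float   # buccolingual semi-axis at the crest
    ax_apex: float
    aspect: float

    def semi_axes(self, z, z_apex, z_crest):
        f = np.clip((z - z_apex) / (z_crest - z_apex), 0.0, 1.0)
        ax = self.ax_apex + (self.ax_crest - self.ax_apex) * f
        return ax, ax * self.aspect


def _layout(params: GeometryParams):
    p = params
    h = p.element_size
    W, L, H = p.corpus_width, p.length, p.corpus_height
    # even cell counts so tooth centres land on grid nodes (exact ring mapping)
    nx = max(4, 2 * int(round(W / (2 * h))))
    if p.corpus_length is None:
        # one even-celled slot per tooth, each tooth centred in its slot
        ny = p.n_teeth * max(4, 2 * int(round(p.tooth_pitch / (2 * h))))
    else:
        ny = max(4, int(round(L / h)))
    hx, hy = W / nx, L / ny
    t = p.pdl_thickness

    def rings(radius_crest, wall_extent, region):
        # ring radii in cells; c3 (the unmapped outer ring that bounds the
        # dense socket wall) is tied to a physical extent so the material
        # geometry is identical at every mesh resolution
        c1 = max(1, int(round(radius_crest / min(hx, hy))))
        c2 = c1 + 1
        c3 = max(c2 + 1, int(round(wall_extent / min(hx, hy))))
        # the mapped PDL outer surface must stay inside the untouched ring c3
        if radius_crest + t >= c3 * min(hx, hy):
            raise ValueError(
                f"degenerate socket geometry at {region}: root radius {radius_crest} mm "
                f"+ PDL does not fit inside the blend ring at element size {h} mm"
            )
        return c1, c2, c3

    wall = p.socket_wall_extent
    if wall is None:
        wall = min(W, L / p.n_teeth) / 2.0
        if p.two_rooted:
            wall = min(wall, p.root_separation / 2.0)
    roots: list[_Root] = []
    for tooth in range(p.n_teeth):
        yc = (tooth + 0.5) * (L / p.n_teeth)
        if p.two_rooted:
            centres = (yc - p.root_separation / 2.0, yc + p.root_separation / 2.0)
        else:
            centres = (yc,)
        for yr in centres:
            c1, c2, c3 = rings(p.root_radius_crest, wall, f"tooth {tooth}")
            roots.append(
                _Root(tooth, nx / 2.0, round(yr / hy), c1, c2, c3,
                      p.root_radius_crest, p.root_radius_apex, p.root_aspect)
            )
    # blend rings must stay inside the corpus and must not overlap
    for r in roots:
        if r.ix - r.c3 < -1e-9 or r.ix + r.c3 > nx + 1e-9:
            raise ValueError(
                f"degenerate socket geometry at tooth {r.tooth}: blend ring exceeds the corpus width"
            )
        if r.iy - r.c3 < -1e-9 or r.iy + r.c3 > ny + 1e-9:
            raise ValueError(
                f"degenerate socket geometry at tooth {r.tooth}: blend ring exceeds the corpus length"
            )
    for a, b in zip(roots, roots[1:]):
        if b.iy - a.iy < a.c3 + b.c3 - 1e-9:
            raise ValueError(
                "degenerate socket geometry: adjacent root blend rings overlap "
                f"(teeth {a.tooth}/{b.tooth}); increase spacing or reduce element size"
            )
    return nx, ny, hx, hy, roots


def _z_lines(params: GeometryParams):
    p = params
    t, h = p.pdl_thickness, p.element_size
    z_apex = p.corpus_height - p.root_length
    seg1 = np.linspace(0.0, z_apex - t, max(1, int(round((z_apex - t) / h))) + 1)
    seg2 = np.linspace(z_apex, p.corpus_height, max(1, int(round(p.root_length / h))) + 1)
    seg3 = np.linspace(p.corpus_height, p.corpus_height + p.crown_height,
                       max(2, int(round(p.crown_height / h))) + 1)
    z = np.concatenate([seg1, seg2, seg3[1:]])
    return z, z_apex


# Kuhn subdivision of a hex (corners indexed by bits z<<2 | y<<1 | x) into six
# positively oriented tets sharing the 0-7 diagonal; conforming across hexes.
_KUHN = np.array([
    (0, 1, 3, 7), (0, 5, 1, 7), (0, 3, 2, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 6, 4, 7),
], dtype=np.int64)


def generate_trabecular_lattice(centroids, volumes, params: GeometryParams, extent=None):
    """Label interior elements as trabecular bone (struts/plates) or pore filling.

    A jittered orthogonal plate lattice is realised by thresholding, at the
    requested bone volume fraction ``1 - lattice_porosity``, the distance of
    each element centroid to its nearest lattice plane.  The threshold is a
    volume-weighted quantile, so the realised bone volume fraction matches
    the target up to element-level quantisation.  Deterministic for a fixed
    seed.

    Returns ``(is_bone, realised_fraction)``.
    """
    if params.lattice_spacing < params.element_size:
        raise ValueError("lattice_spacing must be at least the element size")
    centroids = np.asarray(centroids, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if extent is None:
        extent = centroids.max(axis=0)
    rng = np.random.default_rng(params.seed)
    d = params.lattice_spacing
    score = np.full(len(centroids), np.inf)
    for axis in range(3):
        n_planes = int(np.ceil(extent[axis] / d)) + 1
        planes = (np.arange(n_planes) + 0.5 + 0.3 * rng.uniform(-1, 1, n_planes)) * d
        dist = np.abs(centroids[:, axis][:, None] - planes[None, :]).min(axis=1)
        score = np.minimum(score, dist / d)
    bone_frac = 1.0 - params.lattice_porosity
    order = np.argsort(score, kind="stable")
    cum = np.cumsum(volumes[order])
    k = int(np.searchsorted(cum, bone_frac * cum[-1], side="left"))
    is_bone = np.zeros(len(centroids), dtype=bool)
    is_bone[order[: k + 1]] = True
    if params.lattice_porosity == 0.0:
        is_bone[:] = True
    realised = float(volumes[is_bone].sum() / volumes.sum())
    return is_bone, realised


def _ring_map(coords, root: _Root, hx, hy, z_apex, z_crest, t):
    """Radially remap nodes inside a root's blend ring onto the root/PDL surfaces."""
    di = coords[:, 0] / hx - root.ix
    dj = coords[:, 1] / hy - root.iy
    s = np.maximum(np.abs(di), np.abs(dj))
    sel = (s > 1e-9) & (s < root.c3 - 1e-9)
    if not sel.any():
        return
    di, dj, s = di[sel], dj[sel], s[sel]
    ux, uy = di * hx, dj * hy
    r = np.hypot(ux, uy)
    ct, st = ux / r, uy / r
    ax, ay = root.semi_axes(coords[sel, 2], z_apex, z_crest)
    a = ax * ay / np.sqrt((ay * ct) ** 2 + (ax * st) ** 2)
    ray3 = r * (root.c3 / s)  # distance to the (unmoved) c3 ring along this ray
    rho = np.where(
        s <= root.c1,
        s / root.c1 * a,
        np.where(
            s <= root.c2,
            a + (s - root.c1) / (root.c2 - root.c1) * t,
            (a + t) + (s - root.c2) / (root.c3 - root.c2) * (ray3 - (a + t)),
        ),
    )
    scale = rho / r
    coords[sel, 0] = root.ix * hx + ux * scale
    coords[sel, 1] = root.iy * hy + uy * scale


def build_socket_geometry(params: GeometryParams | None = None, **overrides) -> LabeledMesh:
    """Generate the labelled tooth-in-socket mesh.

    The mesh is conforming (shared nodes across all material interfaces, no
    contact surfaces), carries exactly one of the five material labels per
    element, and is a pure function of the parameters (including the seed,
    which controls only the trabecular lattice jitter).
    """
    p = params if params is not None else GeometryParams()
    if overrides:
        p = replace(p, **overrides)
    p.validate()
    nx, ny, hx, hy, roots = _layout(p)
    z, z_apex = _z_lines(p)
    nz = len(z) - 1
    t = p.pdl_thickness
    crest = p.corpus_height
    W, L = p.corpus_width, p.length
    loaded_tooth = p.n_teeth // 2

    # --- classify hex cells ----------------------------------------------
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (ii + 0.5), (jj + 0.5)
    s_root = np.stack([np.maximum(np.abs(cx - r.ix), np.abs(cy - r.iy)) for r in roots])
    tooth_idx = np.array([r.tooth for r in roots])

    hex_ijk, hex_label, hex_tooth = [], [], []
    code = MATERIAL_CODE
    for k in range(nz):
        zc = 0.5 * (z[k] + z[k + 1])
        lab = np.full((nx, ny), -1, dtype=np.int8)
        tooth2d = np.full((nx, ny), -1, dtype=np.int8)
        if zc > crest:
            # crown layers: only the root core continues upward, so the crown
            # never shares nodes with the alveolar crest (no tooth-bone weld;
            # the PDL ring surfaces at the cervical margin)
            for r, s in zip(roots, s_root):
                inside = s < r.c1
                lab[inside] = code["tooth"]
                tooth2d[inside] = r.tooth
            if p.two_rooted:  # bridge joining the two root stumps of each tooth
                first_layer = z[k] < crest + 1e-9
                for tooth in range(p.n_teeth):
                    rs = [r for r in roots if r.tooth == tooth]
                    lo, hi = min(r.iy for r in rs), max(r.iy for r in rs)
                    bridge = (np.abs(cx - rs[0].ix) <= rs[0].c1 - 1) & (cy >= lo) & (cy <= hi)
                    # furcation: the bridge's first layer is PDL over the
                    # inter-radicular septum, keeping crown and bone apart
                    lab[bridge] = code["pdl"] if first_layer else code["tooth"]
                    tooth2d[bridge] = tooth
        else:
            lab[:] = code["trabecular_bone"]  # provisional bone; refined below
            near_x = (cx * hx < p.cortical_thickness) | (cx * hx > W - p.cortical_thickness)
            shell = near_x | (zc < p.cortical_thickness) | (zc > crest - p.cortical_thickness)
            lab[shell] = code["cortical"]
            # dense (alveolar/cortical) socket wall: a fixed physical ring
            # around each root, identical at every mesh resolution
            if zc > z_apex - t - p.cortical_thickness:
                for r, s in zip(roots, s_root):
                    lab[s < r.c3] = code["cortical"]
            if zc > z_apex:  # root + lateral PDL ring
                for r, s, ti in zip(roots, s_root, tooth_idx):
                    lab[s < r.c1] = code["tooth"]
                    tooth2d[s < r.c1] = ti
                    ring = (s >= r.c1) & (s < r.c2)
                    lab[ring] = code["pdl"]
                    tooth2d[ring] = ti
            elif zc > z_apex - t:  # apical PDL cap
                for r, s, ti in zip(roots, s_root, tooth_idx):
                    cap = s < r.c2
                    lab[cap] = code["pdl"]
                    tooth2d[cap] = ti
        keep = np.argwhere(lab >= 0)
        for i, j in keep:
            hex_ijk.append((i, j, k))
            hex_label.append(lab[i, j])
            hex_tooth.append(tooth2d[i, j])
    hex_ijk = np.asarray(hex_ijk, dtype=np.int64)
    hex_label = np.asarray(hex_label, dtype=np.int8)
    hex_tooth = np.asarray(hex_tooth, dtype=np.int8)

    # --- corner nodes ------------------------------------------------------
    corner_id = np.full((nx + 1, ny + 1, nz + 1), -1, dtype=np.int64)
    di = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    dj = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    dk = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    ci = hex_ijk[:, 0][:, None] + di
    cj = hex_ijk[:, 1][:, None] + dj
    ck = hex_ijk[:, 2][:, None] + dk
    corner_id[ci, cj, ck] = 0
    used = np.argwhere(corner_id == 0)
    corner_id[used[:, 0], used[:, 1], used[:, 2]] = np.arange(len(used))
    coords = np.column_stack([used[:, 0] * hx, used[:, 1] * hy, z[used[:, 2]]])
    for r in roots:
        _ring_map(coords, r, hx, hy, z_apex, crest, t)

    # --- tets ---------------------------------------------------------------
    hex_conn = corner_id[ci, cj, ck]  # (n_hex, 8)
    tets = hex_conn[:, _KUHN].reshape(-1, 4)
    labels = np.repeat(hex_label, 6)
    tooth_of = np.repeat(hex_tooth, 6)

    # --- trabecular lattice --------------------------------------------------
    trab = labels == code["trabecular_bone"]
    vols4 = tet_volumes(coords, tets)
    if np.min(vols4) <= 0:
        worst = np.argsort(vols4)[:5]
        raise ValueError(
            "element quality below threshold: non-positive tet volumes at elements "
            f"{worst.tolist()} (min volume {vols4.min():.3e} mm^3)"
        )
    if trab.any():
        cent = coords[tets[trab]].mean(axis=1)
        if p.trabecular_mode == "structure":
            is_bone, realised = generate_trabecular_lattice(
                cent, vols4[trab], p, extent=(W, L, crest))
            sub = np.where(is_bone, code["trabecular_bone"], code["trabecular_filling"])
            labels[trab] = sub
        else:
            realised = 1.0
    else:
        realised = 0.0

    # --- tet10 ---------------------------------------------------------------
    edges = tets[:, TET10_EDGES].reshape(-1, 2)
    edges.sort(axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid_ids = len(coords) + inv.reshape(-1, 6)
    mid_coords = 0.5 * (coords[uniq[:, 0]] + coords[uniq[:, 1]])
    nodes = np.vstack([coords, mid_coords])
    elements = np.column_stack([tets, mid_ids]).astype(np.int64)

    mesh = LabeledMesh(
        nodes=nodes, elements=elements, labels=labels.astype(np.int8),
        tooth_of=tooth_of.astype(np.int8),
    )
    mesh.meta = {
        "params": p,
        "corpus": (W, L, crest),
        "z_apex": z_apex,
        "crest_z": crest,
        "crown_top_z": crest + p.crown_height,
        "element_size": p.element_size,
        "tooth_centres": [
            (roots[0].ix * hx, float(np.mean([r.iy for r in roots if r.tooth == tt])) * hy)
            for tt in range(p.n_teeth)
        ],
        "crown_radius": p.root_radius_crest,
        "loaded_tooth": loaded_tooth,
        "trabecular_bone_fraction": realised,
    }
    _build_node_sets(mesh, p)
    return mesh


def _build_node_sets(mesh: LabeledMesh, p: GeometryParams) -> None:
    nodes = mesh.nodes
    W, L, crest = mesh.meta["corpus"]
    z_top = mesh.meta["crown_top_z"]
    xc, yc = mesh.meta["tooth_centres"][mesh.meta["loaded_tooth"]]
    r_crown = mesh.meta["crown_radius"]
    tol = 1e-8

    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    sets = {
        "cut_mesial": np.flatnonzero(np.abs(y) < tol),
        "cut_distal": np.flatnonzero(np.abs(y - L) < tol),
        "outer_lingual": np.flatnonzero(np.abs(x) < tol),
        "outer_buccal": np.flatnonzero(np.abs(x - W) < tol),
        "outer_base": np.flatnonzero(np.abs(z) < tol),
    }
    for name, yv in (("base_mesial", 0.0), ("base_distal", L)):
        # fixed-footprint area patch on the inferior surface at each cut face:
        # refinement adds nodes but keeps the supported region (and hence the
        # global load path) unchanged
        sets[name] = np.flatnonzero(
            (np.abs(y - yv) <= p.base_patch_depth + tol) & (np.abs(z) < tol)
            & (np.abs(x - W / 2.0) <= p.base_patch_halfwidth + tol))

    rxy = np.hypot(x - xc, y - yc)
    sets["occlusal_patch"] = np.flatnonzero(
        (np.abs(z - z_top) < tol) & (rxy <= p.patch_radius + tol))
    z_mid = crest + p.crown_height / 2.0
    on_crown_side = (z > crest + tol) & (rxy >= 0.95 * r_crown)
    for name, centre in (
        ("buccal_patch", (xc + r_crown, yc, z_mid)),
        ("contact_mesial", (xc, yc - r_crown, z_mid)),
        ("contact_distal", (xc, yc + r_crown, z_mid)),
    ):
        d = np.linalg.norm(nodes - np.asarray(centre), axis=1)
        # fixed physical slack so the patch footprint is mesh-independent
        sets[name] = np.flatnonzero(on_crown_side & (d <= p.patch_radius + 0.75))
    for name, arr in sets.items():
        if name.endswith("_patch") or name.startswith("contact") or name.startswith("base"):
            if len(arr) == 0:
                raise ValueError(f"geometry produced an empty node set {name!r}")
    mesh.node_sets = sets


def build_block(nx: int, ny: int, nz: int, size=(1.0, 1.0, 1.0),
                label: str = "cortical") -> LabeledMesh:
    """Structured tet10 mesh of a rectangular block (benchmarks, patch tests).

    Node sets tag the six faces (``x0``, ``x1``, ``y0``, ``y1``, ``z0``, ``z1``).
    """
    sx, sy, sz = size
    xs = np.linspace(0, sx, nx + 1)
    ys = np.linspace(0, sy, ny + 1)
    zs = np.linspace(0, sz, nz + 1)
    cid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    di = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    dj = np.array([0, 0, 1, 1, 0, 0, 1, 1])
    dk = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    hexes = cid[ii[:, None] + di, jj[:, None] + dj, kk[:, None] + dk]
    tets = hexes[:, _KUHN].reshape(-1, 4)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    edges = tets[:, TET10_EDGES].reshape(-1, 2)
    edges.sort(axis=1)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    nodes = np.vstack([pts, 0.5 * (pts[uniq[:, 0]] + pts[uniq[:, 1]])])
    elements = np.column_stack([tets, len(pts) + inv.reshape(-1, 6)]).astype(np.int64)
    n_el = len(elements)
    mesh = LabeledMesh(
        nodes=nodes, elements=elements,
        labels=np.full(n_el, MATERIAL_CODE[label], dtype=np.int8),
        tooth_of=np.full(n_el, -1, dtype=np.int8),
    )
    tol = 1e-9
    mesh.node_sets = {
        "x0": np.flatnonzero(np.abs(nodes[:, 0]) < tol),
        "x1": np.flatnonzero(np.abs(nodes[:, 0] - sx) < tol),
        "y0": np.flatnonzero(np.abs(nodes[:, 1]) < tol),
        "y1": np.flatnonzero(np.abs(nodes[:, 1] - sy) < tol),
        "z0": np.flatnonzero(np.abs(nodes[:, 2]) < tol),
        "z1": np.flatnonzero(np.abs(nodes[:, 2] - sz) < tol),
    }
    return mesh


def analytic_volume(params: GeometryParams) -> float:
    """CSG volume of the synthetic solid: corpus block plus cylindrical crowns.

    Valid for single-rooted teeth (the crown is a cylinder of radius
    root_radius_crest + pdl_thickness).  The faceted mesh volume falls short
    of this by the sagitta of the crown polygon only (well under 2 %).
    """
    p = params
    box = p.corpus_width * p.length * p.corpus_height
    r = p.root_radius_crest + p.pdl_thickness
    crown = np.pi * r * (r * p.root_aspect) * p.crown_height
    return float(box + p.n_teeth * crown)
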