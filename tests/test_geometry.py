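"""Synthetic tooth-in-socket geometry: labels, PDL shell, lattice, determinism."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from alveofem.geometry import (GeometryParams, analytic_volume, build_socket_geometry,
                               generate_trabecular_lattice)
from alveofem.meshdata import (MATERIAL_CODE, check_conforming, interface_faces,
                               tet_volumes, TET_FACES)


def _facet_points(mesh, mat_a, mat_b, subdivide=4):
    """Sample points on the interface facets between two materials."""
    elems, locals_, _ = interface_faces(mesh, mat_a, mat_b)
    pts = []
    bary = []
    for i in range(subdivide + 1):
        for j in range(subdivide + 1 - i):
            k = subdivide - i - j
            bary.append((i / subdivide, j / subdivide, k / subdivide))
    bary = np.asarray(bary)
    for fi in range(4):
        sel = locals_ == fi
        if not sel.any():
            continue
        tri = mesh.elements[elems[sel]][:, TET_FACES[fi]]
        p = mesh.nodes[tri]
        pts.append(np.einsum("bk,nkd->nbd", bary, p).reshape(-1, 3))
    return np.vstack(pts)


def test_default_mesh_is_conforming_and_fully_labelled():
    mesh = build_socket_geometry()
    check_conforming(mesh)
    assert mesh.labels.min() >= 0 and mesh.labels.max() <= 4
    assert np.all(tet_volumes(mesh.nodes, mesh.elements) > 0)
    # mid-edge nodes at edge midpoints
    conn = mesh.elements
    for m, (a, b) in enumerate(((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))):
        mid = mesh.nodes[conn[:, 4 + m]]
        expect = 0.5 * (mesh.nodes[conn[:, a]] + mesh.nodes[conn[:, b]])
        np.testing.assert_allclose(mid, expect, atol=1e-12)


def _point_triangle_distance(p, a, b, c):
    """Exact distance from points p to triangles (a, b, c), pairwise."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    closest = np.empty_like(p)
    # vertex regions
    closest[:] = a
    m = (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    m = (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    # edge AB
    v = d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest[m] = a[m] + v[m, None] * ab[m]
    # edge AC
    w = d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest[m] = a[m] + w[m, None] * ac[m]
    # edge BC
    w2 = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) + (d5 - d6), 1.0)
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest[m] = b[m] + w2[m, None] * (c[m] - b[m])
    # interior
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v_i, w_i = vb / denom, vc / denom
    m = (va > 0) & (vb > 0) & (vc > 0)
    closest[m] = a[m] + v_i[m, None] * ab[m] + w_i[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1)


def test_pdl_shell_thickness_within_band():
    """Every local PDL thickness measurement lies within [0.20, 0.30] mm."""
    mesh = build_socket_geometry()
    elems, locals_, _ = interface_faces(mesh, "cortical", "pdl")
    tris = np.vstack([mesh.elements[elems[locals_ == fi]][:, TET_FACES[fi]]
                      for fi in range(4) if (locals_ == fi).any()])
    ta, tb, tc = (mesh.nodes[tris[:, k]] for k in range(3))
    centroids = (ta + tb + tc) / 3.0
    root_pts = _facet_points(mesh, "tooth", "pdl", subdivide=2)
    k = min(16, len(tris))
    _, cand = cKDTree(centroids).query(root_pts, k=k)
    d = np.full(len(root_pts), np.inf)
    for col in range(k):
        idx = cand[:, col]
        d = np.minimum(d, _point_triangle_distance(root_pts, ta[idx], tb[idx], tc[idx]))
    assert d.min() >= 0.20, f"thinnest PDL measurement {d.min():.3f} mm"
    assert d.max() <= 0.30, f"thickest PDL measurement {d.max():.3f} mm"


def test_mesh_volume_matches_csg_within_two_percent():
    params = GeometryParams()
    mesh = build_socket_geometry(params)
    vol = mesh.volumes().sum()
    ref = analytic_volume(params)
    assert abs(vol - ref) / ref < 0.02


def test_geometry_deterministic_for_fixed_seed():
    a = build_socket_geometry(GeometryParams(seed=7))
    b = build_socket_geometry(GeometryParams(seed=7))
    np.testing.assert_array_equal(a.elements, b.elements)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_allclose(a.nodes, b.nodes)
    c = build_socket_geometry(GeometryParams(seed=8))
    assert not np.array_equal(a.labels, c.labels)  # lattice jitter moved


def test_zero_porosity_fills_all_pores():
    mesh = build_socket_geometry(GeometryParams(lattice_porosity=0.0))
    assert len(mesh.elements_of("trabecular_filling")) == 0


def test_lattice_volume_fraction_matches_porosity():
    mesh = build_socket_geometry(GeometryParams(lattice_porosity=0.5))
    vols = np.abs(mesh.volumes())
    vb = vols[mesh.elements_of("trabecular_bone")].sum()
    vf = vols[mesh.elements_of("trabecular_filling")].sum()
    frac = vb / (vb + vf)
    assert abs(frac - 0.5) <= 0.1


def test_lattice_struts_are_connected():
    mesh = build_socket_geometry(GeometryParams(lattice_porosity=0.5))
    import scipy.sparse as sp
    idx = mesh.elements_of("trabecular_bone")
    conn = mesh.elements[idx, :4]
    # graph on elements sharing nodes
    node_of = {}
    rows, cols = [], []
    for e, quad in enumerate(conn):
        for n in quad:
            node_of.setdefault(n, []).append(e)
    for elems in node_of.values():
        for e in elems[1:]:
            rows.append(elems[0])
            cols.append(e)
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(idx), len(idx)))
    n_comp, _ = sp.csgraph.connected_components(g, directed=False)
    assert n_comp == 1


def test_lattice_spacing_below_element_size_rejected():
    with pytest.raises(ValueError, match="lattice_spacing"):
        build_socket_geometry(GeometryParams(lattice_spacing=1.0, element_size=1.5))


def test_lattice_generator_deterministic():
    params = GeometryParams(seed=3)
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 12, size=(4000, 3))
    vols = np.ones(4000)
    a1, f1 = generate_trabecular_lattice(pts, vols, params, extent=(12, 12, 30))
    a2, f2 = generate_trabecular_lattice(pts, vols, params, extent=(12, 12, 30))
    np.testing.assert_array_equal(a1, a2)
    assert f1 == f2
    assert abs(f1 - 0.5) < 0.05  # volume-weighted quantile hits the target


def test_degenerate_parameters_rejected():
    with pytest.raises(ValueError):
        GeometryParams(pdl_thickness=2.0).validate()  # thicker than apex radius
    with pytest.raises(ValueError):
        GeometryParams(n_teeth=5).validate()
    with pytest.raises(ValueError, match="degenerate socket"):
        # root + PDL cannot fit inside the blend ring on a tiny corpus
        build_socket_geometry(GeometryParams(corpus_width=6.0, root_radius_crest=3.5))


def test_three_teeth_and_two_rooted_meshes_build():
    m3 = build_socket_geometry(GeometryParams(n_teeth=3, corpus_height=18.0,
                                              root_length=7.5))
    assert len(np.unique(m3.tooth_of[m3.elements_of("pdl")])) == 3
    m2 = build_socket_geometry(GeometryParams(
        two_rooted=True, root_radius_crest=1.8, root_radius_apex=0.9,
        root_separation=6.0, element_size=0.75, corpus_height=15.0,
        root_length=7.5, corpus_width=9.0, tooth_pitch=12.0))
    check_conforming(m2)
    assert np.all(tet_volumes(m2.nodes, m2.elements) > 0)
    # the two root stumps merge into one crown (single connected tooth)
    assert len(m2.elements_of("tooth")) > 0


def test_node_sets_present_and_on_their_surfaces():
    mesh = build_socket_geometry()
    W, L, crest = mesh.meta["corpus"]
    assert np.allclose(mesh.nodes[mesh.set_nodes("cut_mesial"), 1], 0.0)
    assert np.allclose(mesh.nodes[mesh.set_nodes("outer_buccal"), 0], W)
    for name in ("occlusal_patch", "buccal_patch", "contact_mesial",
                 "contact_distal", "base_mesial", "base_distal"):
        assert len(mesh.set_nodes(name)) > 0
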