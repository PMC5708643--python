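"""Finite-element core: elements, assembly, solving, strain recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alveofem.fem import (ConstraintSet, Material, assemble, elasticity_matrix,
                          fibre_stiffness_matrix, link_stiffness, nodal_strains,
                          principal_strains, recover_strains, solve_linear,
                          solve_tension_only, tet10_stiffness, von_mises_strain)
from alveofem.geometry import build_block
from alveofem.meshdata import MATERIAL_CODE, TET10_EDGES

# degree-5 Keast quadrature (14 points) for the independent stiffness oracle
_KEAST = []
for b, w in ((0.3108859192633005, 0.1126879257180162),
             (0.0927352503108912, 0.0734930431163619)):
    a = 1.0 - 3 * b
    for pt in ([a, b, b, b], [b, a, b, b], [b, b, a, b], [b, b, b, a]):
        _KEAST.append((pt, w))
c, d = 0.0455037041256497, 0.4544962958743503
for pt in ([c, c, d, d], [c, d, c, d], [c, d, d, c],
           [d, c, c, d], [d, c, d, c], [d, d, c, c]):
    _KEAST.append((pt, 0.0425460207770812))


def _random_tet10(seed):
    rng = np.random.default_rng(seed)
    corners = rng.uniform(-1, 1, (4, 3))
    j = np.linalg.det(np.array([corners[1] - corners[0], corners[2] - corners[0],
                                corners[3] - corners[0]]))
    if abs(j) < 0.1:
        return _random_tet10(seed + 1000)
    if j < 0:
        corners[[1, 2]] = corners[[2, 1]]
    mids = np.array([(corners[a] + corners[b]) / 2 for a, b in TET10_EDGES])
    return np.vstack([corners, mids])


def _oracle_stiffness(coords, D):
    """Brute-force BtDB integration with symbolically derived shape gradients."""
    import sympy as sp
    xi, eta, zeta = sp.symbols("xi eta zeta")
    L = [1 - xi - eta - zeta, xi, eta, zeta]
    N = [Li * (2 * Li - 1) for Li in L]
    N += [4 * L[a] * L[b] for a, b in TET10_EDGES]
    grads = sp.lambdify((xi, eta, zeta),
                        sp.Matrix([[sp.diff(n, v) for v in (xi, eta, zeta)]
                                   for n in N]), "numpy")
    p0 = coords[0]
    J = np.stack([coords[1] - p0, coords[2] - p0, coords[3] - p0], axis=1)
    detJ = np.linalg.det(J)
    invJ = np.linalg.inv(J)
    K = np.zeros((30, 30))
    for (bary, w) in _KEAST:
        g = np.asarray(grads(bary[1], bary[2], bary[3]), dtype=float) @ invJ
        B = np.zeros((6, 30))
        cols = 3 * np.arange(10)
        B[0, cols] = g[:, 0]
        B[1, cols + 1] = g[:, 1]
        B[2, cols + 2] = g[:, 2]
        B[3, cols] = g[:, 1]
        B[3, cols + 1] = g[:, 0]
        B[4, cols + 1] = g[:, 2]
        B[4, cols + 2] = g[:, 1]
        B[5, cols] = g[:, 2]
        B[5, cols + 2] = g[:, 0]
        K += w * (detJ / 6.0) * B.T @ D @ B
    return K


def test_elasticity_matrix_closed_form_values():
    D = elasticity_matrix(Material(17000.0, 0.3))
    assert D[0, 0] == pytest.approx(17000 * 0.7 / (1.3 * 0.4))  # ~22884.6
    D0 = elasticity_matrix(Material(200.0, 0.0))
    assert D0[0, 0] == pytest.approx(200.0)
    assert D0[3, 3] == pytest.approx(100.0)
    assert np.count_nonzero(D0 - np.diag(np.diag(D0))) == 0
    # nearly incompressible PDL matrix stays positive definite
    Dp = elasticity_matrix(Material(1.0, 0.45))
    assert np.linalg.eigvalsh(Dp).min() > 0
    with pytest.raises(ValueError):
        Material(1.0, 0.5)
    with pytest.raises(ValueError):
        Material(-1.0, 0.3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_tet10_stiffness_matches_brute_force_quadrature(seed):
    coords = _random_tet10(seed)
    D = elasticity_matrix(Material(1.0, 0.0 if seed == 0 else 0.3))
    K = tet10_stiffness(coords, D)
    K_ref = _oracle_stiffness(coords, D)
    scale = np.abs(K_ref).max()
    np.testing.assert_allclose(K, K_ref, atol=1e-10 * scale)


def test_tet10_rigid_body_modes_and_degenerate_error():
    coords = _random_tet10(5)
    K = tet10_stiffness(coords, elasticity_matrix(Material(1000.0, 0.3)))
    w = np.linalg.eigvalsh(K)
    assert np.all(np.abs(w[:6]) < 1e-9 * w[-1])  # six zero-energy modes
    assert w[6] > 1e-6 * w[-1]
    bad = coords.copy()
    bad[3] = bad[0]  # flattened tet
    with pytest.raises(ValueError, match="Jacobian"):
        tet10_stiffness(bad, elasticity_matrix(Material(1.0, 0.3)))


def test_link_stiffness_closed_form_and_inactive():
    K, n, L0 = link_stiffness([0, 0, 0], [0, 0, 0.3], E=1000.0, area=0.01)
    assert L0 == pytest.approx(0.3)
    assert K[2, 2] == pytest.approx(1000 * 0.01 / 0.3)  # 33.33 N/mm
    np.testing.assert_allclose(K[:3, :3], -K[:3, 3:])
    K0, _, _ = link_stiffness([0, 0, 0], [0, 0, 0.3], 1000.0, 0.01, active=False)
    assert np.all(K0 == 0)
    with pytest.raises(ValueError, match="coincident"):
        link_stiffness([1, 1, 1], [1, 1, 1], 1.0, 1.0)


def test_assembly_is_order_independent():
    mesh = build_block(2, 2, 2)
    mats = {"cortical": Material(100.0, 0.3)}
    K1 = assemble(mesh, mats)
    rng = np.random.default_rng(0)
    perm = rng.permutation(mesh.n_elements)
    shuffled = type(mesh)(nodes=mesh.nodes, elements=mesh.elements[perm],
                          labels=mesh.labels[perm], tooth_of=mesh.tooth_of[perm])
    K2 = assemble(shuffled, mats)
    assert abs(K1 - K2).max() < 1e-12 * abs(K1).max()


def test_assembly_requires_all_materials():
    mesh = build_block(1, 1, 1)
    mesh.labels[:3] = MATERIAL_CODE["pdl"]
    with pytest.raises(ValueError, match="pdl"):
        assemble(mesh, {"cortical": Material(1.0, 0.3)})


def test_patch_fields_reproduced_exactly():
    """Prescribed linear and quadratic equilibrium fields solved to ~machine zero."""
    from alveofem.verification import patch_test
    res = patch_test()
    assert res["linear_field_error"] < 1e-9
    assert res["quadratic_field_error"] < 1e-9


def test_uniaxial_block_and_equilibrium():
    mesh = build_block(2, 2, 2, (1.0, 1.0, 1.0))
    E = 100.0
    K = assemble(mesh, {"cortical": Material(E, 0.0)})
    bottom, top = mesh.set_nodes("z0"), mesh.set_nodes("z1")
    cs = ConstraintSet.from_nodes(bottom, [2]).merge(
        ConstraintSet.from_nodes([bottom[0]], [0, 1])).merge(
        ConstraintSet.from_nodes([bottom[-1]], [1]))
    f = np.zeros(3 * mesh.n_nodes)
    # consistent equal-split of a unit pressure is not needed; total force -1
    f[3 * top + 2] = -1.0 / len(top)
    u, r = solve_linear(K, f, cs)
    eps = recover_strains(mesh, u.reshape(-1, 3))
    # equilibrium: applied + reactions balance per component
    for comp in range(3):
        assert abs(f[comp::3].sum() + r[comp::3].sum()) < 1e-9
    # mean axial strain equals sigma/E (local variation from the crude load split)
    assert eps[:, 2].mean() == pytest.approx(-1.0 / E, rel=0.02)


def test_zero_load_gives_zero_displacement():
    mesh = build_block(1, 1, 1)
    K = assemble(mesh, {"cortical": Material(10.0, 0.3)})
    cs = ConstraintSet.from_nodes(mesh.set_nodes("z0"), [0, 1, 2])
    u, r = solve_linear(K, np.zeros(3 * mesh.n_nodes), cs)
    assert np.all(u == 0) and np.all(r == 0)


def test_unconstrained_system_raises():
    mesh = build_block(1, 1, 1)
    K = assemble(mesh, {"cortical": Material(10.0, 0.3)})
    f = np.zeros(3 * mesh.n_nodes)
    f[2] = 1.0
    with pytest.raises(ValueError, match="singular|constrain"):
        solve_linear(K, f, ConstraintSet())


def test_series_bars_match_closed_form():
    from alveofem.verification import series_bar_check
    res = series_bar_check()
    assert res["relative_error"] < 1e-12


def test_tension_only_all_tension_equals_linear():
    from alveofem.verification import _toy_fibre_model
    mesh, K0, fibres, f, cs = _toy_fibre_model()
    f_up = np.zeros_like(f)
    top = mesh.set_nodes("z1")
    f_up[3 * top + 2] = 1.0 / len(top)  # pure pull: every fibre elongates
    sol = solve_tension_only(mesh, K0, fibres, f_up, cs)
    assert sol.active.all()
    Kf = fibre_stiffness_matrix(mesh.nodes, fibres.bone_node, fibres.root_node,
                                fibres.E, fibres.area, sol.active, K0.shape[0])
    u_lin, _ = solve_linear(K0 + Kf, f_up, cs)
    np.testing.assert_allclose(sol.u.ravel(), u_lin, atol=1e-12)


def test_tension_only_compressed_fibres_carry_nothing():
    from alveofem.verification import _toy_fibre_model
    mesh, K0, fibres, f, cs = _toy_fibre_model()
    f_dn = np.zeros_like(f)
    top = mesh.set_nodes("z1")
    f_dn[3 * top + 2] = -1.0 / len(top)  # pure push: every fibre shortens
    sol = solve_tension_only(mesh, K0, fibres, f_dn, cs)
    assert not sol.active.any()
    assert np.all(sol.elongations <= 1e-12)


def test_strain_recovery_uniaxial_and_objectivity():
    mesh = build_block(2, 2, 2)
    lam = 1e-3
    u = np.zeros((mesh.n_nodes, 3))
    u[:, 2] = lam * mesh.nodes[:, 2]
    eps = recover_strains(mesh, u)
    pr = principal_strains(eps)
    np.testing.assert_allclose(pr[:, 0], lam, atol=1e-12)
    np.testing.assert_allclose(pr[:, 1:], 0.0, atol=1e-12)
    # small rigid rotation produces no strain
    theta = 1e-6
    u_rot = np.column_stack([-theta * mesh.nodes[:, 1], theta * mesh.nodes[:, 0],
                             np.zeros(mesh.n_nodes)])
    eps_rot = recover_strains(mesh, u_rot)
    assert np.abs(eps_rot).max() < 1e-8


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e-2, 1e-2), min_size=6, max_size=6))
def test_principal_strains_match_characteristic_roots(voigt):
    eps = np.asarray(voigt)
    pr = principal_strains(eps)[0]
    assert pr[0] >= pr[1] >= pr[2]
    T = np.array([[eps[0], eps[3] / 2, eps[5] / 2],
                  [eps[3] / 2, eps[1], eps[4] / 2],
                  [eps[5] / 2, eps[4] / 2, eps[2]]])
    roots = np.sort(np.roots(np.poly(T)).real)[::-1]
    np.testing.assert_allclose(pr, roots, atol=1e-10)
    # von Mises strain vanishes for pure volumetric states
    vol = von_mises_strain(np.array([2e-3, 2e-3, 2e-3, 0, 0, 0]))
    assert vol == pytest.approx(0.0, abs=1e-15)


def test_nodal_averaging_is_same_material_only():
    mesh = build_block(2, 1, 1, (2.0, 1.0, 1.0))
    cent = mesh.nodes[mesh.elements[:, :4]].mean(axis=1)
    mesh.labels[cent[:, 0] > 1.0] = MATERIAL_CODE["pdl"]
    es = np.zeros((mesh.n_elements, 6))
    es[mesh.labels == MATERIAL_CODE["pdl"], 0] = 1.0  # unit strain only in PDL
    vals, mask = nodal_strains(mesh, es, labels=("cortical",))
    assert np.all(vals[mask] == 0.0)  # PDL strain never bleeds into bone nodes
    vals_p, mask_p = nodal_strains(mesh, es, labels=("pdl",))
    np.testing.assert_allclose(vals_p[mask_p][:, 0], 1.0)
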