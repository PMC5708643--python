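"""Load cases and boundary conditions."""

import numpy as np
import pytest

from alveofem.fem import solve_linear
from alveofem.loads import build_constraints, build_load
from alveofem.variants import make_variant, solve_variant


@pytest.fixture(scope="module")
def small(small_model):
    return small_model


def test_resultant_forces(small):
    mesh = small[0]
    occ = build_load(mesh, "occlusal")
    f = occ.force_vector(mesh.n_nodes)
    np.testing.assert_allclose([f[0::3].sum(), f[1::3].sum(), f[2::3].sum()],
                               [0.0, 0.0, -500.0], atol=1e-9)
    bl = build_load(mesh, "orth_buccolingual")
    f = bl.force_vector(mesh.n_nodes)
    np.testing.assert_allclose([f[0::3].sum(), f[1::3].sum(), f[2::3].sum()],
                               [-1.0, 0.0, 0.0], atol=1e-12)
    md = build_load(mesh, "orth_mesiodistal", total_force=2.0)
    f = md.force_vector(mesh.n_nodes)
    assert f[1::3].sum() == pytest.approx(-2.0)


def test_orthodontic_constraints_drop_crown_contacts(small):
    mesh = small[0]
    occ = build_constraints(mesh, "occlusal")
    orth = build_constraints(mesh, "orth_mesiodistal")
    contacts = np.concatenate([mesh.set_nodes("contact_mesial"),
                               mesh.set_nodes("contact_distal")])
    contact_dofs = 3 * contacts + 1
    assert np.all(np.isin(contact_dofs, occ.dofs))
    assert not np.any(np.isin(contact_dofs, orth.dofs))
    # removing the contacts is the only difference
    assert np.array_equal(np.setdiff1d(occ.dofs, orth.dofs),
                          np.unique(contact_dofs))
    with pytest.raises(ValueError, match="unknown load case"):
        build_constraints(mesh, "torsion")


def test_all_cases_solve_without_rigid_body_modes(small):
    """Constraints remove every rigid mode: solves succeed, equilibrium holds."""
    mesh, interfaces, fibres, cache = small
    for name in ("occlusal", "orth_mesiodistal", "orth_buccolingual"):
        case = build_load(mesh, name)
        sol = solve_variant(mesh, make_variant("solid+bulk"), case, cache)
        for comp in range(3):
            total = sol.f[comp::3].sum() + sol.reactions[comp::3].sum()
            assert abs(total) < 1e-6 * np.linalg.norm(sol.f)


def test_orthodontic_solution_scales_linearly(small):
    """Without tension-only state changes the response is exactly linear."""
    mesh, interfaces, fibres, cache = small
    case1 = build_load(mesh, "orth_buccolingual", total_force=1.0)
    case2 = build_load(mesh, "orth_buccolingual", total_force=2.0)
    v = make_variant("solid+structure")
    s1 = solve_variant(mesh, v, case1, cache)
    s2 = solve_variant(mesh, v, case2, cache)
    np.testing.assert_allclose(2.0 * s1.u, s2.u, rtol=1e-6, atol=1e-12)
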