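"""Strain profiles, difference fields and summaries."""

import numpy as np
import pytest

from alveofem.analysis import (difference_field, socket_profile, summarise,
                               vertical_profile)


def test_difference_field_self_and_antisymmetry(occlusal_solutions):
    _, sols = occlusal_solutions
    a = sols["solid+structure"]
    b = sols["none+structure"]
    zero = difference_field(a, a)
    assert np.all(zero.d_e1 == 0) and np.all(zero.d_e3 == 0)
    ab = difference_field(a, b, ("solid", "none"))
    ba = difference_field(b, a, ("none", "solid"))
    np.testing.assert_allclose(ab.d_e1 + ba.d_e1, 0.0, atol=1e-12)
    np.testing.assert_allclose(ab.d_e3 + ba.d_e3, 0.0, atol=1e-12)


def test_difference_field_requires_same_mesh(occlusal_solutions, small_model):
    _, sols = occlusal_solutions
    from alveofem.loads import build_load
    from alveofem.variants import make_variant, solve_variant
    mesh_s, _, _, cache_s = small_model
    other = solve_variant(mesh_s, make_variant("solid+bulk"),
                          build_load(mesh_s, "occlusal"), cache_s)
    with pytest.raises(ValueError, match="same mesh"):
        difference_field(sols["solid+structure"], other)


def test_vertical_profile_structure(default_model, occlusal_solutions):
    mesh = default_model[0]
    _, sols = occlusal_solutions
    prof = vertical_profile(mesh, sols["solid+structure"], "buccal")
    assert len(prof) >= 5
    assert np.all(np.diff(prof.positions) > 0)
    # starts at the superior-most node of the buccal surface (the crest)
    assert mesh.nodes[prof.nodes[0], 2] == pytest.approx(mesh.meta["crest_z"])
    with pytest.raises(ValueError):
        vertical_profile(mesh, sols["solid+structure"], "mesial")


def test_profiles_are_pure_functions(default_model, occlusal_solutions):
    mesh = default_model[0]
    _, sols = occlusal_solutions
    p1 = vertical_profile(mesh, sols["none+structure"], "lingual")
    p2 = vertical_profile(mesh, sols["none+structure"], "lingual")
    np.testing.assert_array_equal(p1.nodes, p2.nodes)
    np.testing.assert_allclose(p1.e3, p2.e3)


def test_buccal_lingual_symmetry_of_symmetric_variant(default_model, occlusal_solutions):
    """solid+bulk is buccolingually symmetric: the two profiles mirror closely."""
    mesh = default_model[0]
    _, sols = occlusal_solutions
    pb = vertical_profile(mesh, sols["solid+bulk"], "buccal")
    pl = vertical_profile(mesh, sols["solid+bulk"], "lingual")
    n = min(len(pb), len(pl))
    scale = np.abs(pl.e3[:n]).max()
    # discretisation asymmetry of the tet split bounds the mismatch
    assert np.median(np.abs(pb.e3[:n] - pl.e3[:n])) < 0.05 * scale


def test_socket_profile_sides_and_ordering(default_model, orthodontic_solutions):
    mesh, interfaces, _, _ = default_model
    _, sols = orthodontic_solutions
    for side in ("buccal", "lingual", "mesial", "distal"):
        prof = socket_profile(mesh, sols["solid+structure"], interfaces, side)
        assert len(prof) >= 5
        z = mesh.nodes[prof.nodes, 2]
        assert np.all(np.diff(z) < 1e-9)  # crest -> apex
    with pytest.raises(ValueError):
        socket_profile(mesh, sols["solid+structure"], interfaces, "top")


def test_summary_table(default_model, occlusal_solutions):
    mesh, interfaces, _, _ = default_model
    case, sols = occlusal_solutions
    table = summarise(mesh, interfaces,
                      {(vid, "occlusal"): s for vid, s in sols.items()},
                      {"occlusal": case})
    assert len(table) == len(sols)
    assert "crown_displacement_mm" in table.columns
    assert (table["crown_displacement_mm"] > 0).all()
    # peaks are 95th percentiles, never above the maxima
    for side in ("buccal", "lingual"):
        assert (table[f"{side}_e3_peak_ue"] <= table[f"{side}_e3_max_ue"] + 1e-9).all()
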