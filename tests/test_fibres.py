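"""PDL fibre network: grouping, crossed pairs, areas, geometry."""

import warnings

import numpy as np
import pytest

from alveofem.fibres import (FIBRE_GROUPS, FibreNetworkParams, assign_fibre_groups,
                             build_fibre_network, fibre_area)
from alveofem.geometry import GeometryParams, build_socket_geometry
from alveofem.meshdata import tag_interfaces


@pytest.fixture(scope="module")
def cylinder_socket():
    """Untapered socket: fibre lengths and volumes have closed-form references."""
    mesh = build_socket_geometry(GeometryParams(root_radius_crest=2.6,
                                                root_radius_apex=2.6))
    return mesh, tag_interfaces(mesh)


def test_group_assignment_boundaries():
    splits = (0.10, 0.25, 0.90)
    assert FIBRE_GROUPS[assign_fibre_groups(0.0, splits)] == "crestal"
    assert FIBRE_GROUPS[assign_fibre_groups(0.5, splits)] == "oblique"
    assert FIBRE_GROUPS[assign_fibre_groups(1.0, splits)] == "apical"
    assert FIBRE_GROUPS[assign_fibre_groups(0.15, splits)] == "horizontal"
    with pytest.raises(ValueError):
        assign_fibre_groups(1.5, splits)


def test_fibre_area_rule_and_degenerate_limit():
    assert fibre_area(0.02, 0.6) == pytest.approx(0.006)
    assert fibre_area(0.02, 0.0) == 0.0


def test_crossed_pairs_reference_each_other(cylinder_socket):
    mesh, interfaces = cylinder_socket
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = build_fibre_network(mesh, interfaces)
    assert len(fs) % 2 == 0
    # cross partners are mutual and distinct
    assert np.all(fs.partner[fs.partner] == np.arange(len(fs)))
    assert np.all(fs.partner != np.arange(len(fs)))
    # the pair shares its bone-side node and its cross-section
    np.testing.assert_array_equal(fs.bone_node, fs.bone_node[fs.partner])
    np.testing.assert_allclose(fs.area, fs.area[fs.partner])
    # fibres attach only to interface nodes, never inside the PDL volume
    t = interfaces[0]
    assert np.all(np.isin(fs.bone_node, t.bone_nodes))
    assert np.all(np.isin(fs.root_node, t.root_nodes))


def test_every_fibre_crosses_the_pdl_gap(cylinder_socket):
    mesh, interfaces = cylinder_socket
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = build_fibre_network(mesh, interfaces)
    L0 = fs.rest_lengths(mesh)
    assert L0.min() >= 0.8 * 0.25


def test_horizontal_fibres_perpendicular_to_cylinder_wall(cylinder_socket):
    """With 0 degree inclination, mid-depth fibres span just the PDL gap."""
    mesh, interfaces = cylinder_socket
    params = FibreNetworkParams(band_splits=(0.02, 0.05, 0.95), oblique_angle=0.0,
                                crestal_angle=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = build_fibre_network(mesh, interfaces, params)
    oblique = fs.group == 2  # the 0-degree "oblique" band covers the wall
    L0 = fs.rest_lengths(mesh)[oblique]
    assert len(L0) > 100
    # radially aligned node pairs span exactly the PDL gap; the remainder
    # connect to the nearest admissible node on the faceted interface, whose
    # node-to-node distance exceeds the layer thickness by up to ~60%
    assert np.percentile(L0, 25) == pytest.approx(0.25, rel=0.10)
    assert L0.min() >= 0.8 * 0.25 and L0.max() <= 1.8 * 0.25
    # volume bookkeeping: sum(A L0) = phi * (tributary area) * t_pdl up to
    # the same faceting factor
    t = interfaces[0]
    vol = (fs.area * fs.rest_lengths(mesh))[oblique].sum()
    attached = np.isin(t.bone_nodes, fs.bone_node[oblique])
    ref = 0.60 * t.bone_areas[attached].sum() * 0.25
    assert vol == pytest.approx(ref, rel=0.3)


def test_network_mirror_symmetry(cylinder_socket):
    """The socket is mirror-symmetric in y; fibre counts match across halves."""
    mesh, interfaces = cylinder_socket
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fs = build_fibre_network(mesh, interfaces)
    yc = mesh.meta["tooth_centres"][0][1]
    y = mesh.nodes[fs.bone_node][:, 1]
    assert (y > yc + 1e-9).sum() == (y < yc - 1e-9).sum()


def test_reference_fibre_density_of_the_loaded_molar(default_model):
    """The default network approximates ~1000 crossed pairs on the loaded molar."""
    mesh, interfaces, fibres, cache = default_model
    assert 600 <= len(fibres) / 2 <= 1600


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        FibreNetworkParams(volume_fraction=1.5).validate()
    with pytest.raises(ValueError):
        FibreNetworkParams(band_splits=(0.5, 0.2, 0.9)).validate()
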