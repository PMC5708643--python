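"""Shared fixtures: meshes and solved load cases reused across test modules.

The default single-molar model is expensive to solve, so solutions are
computed once per session and shared; small meshes are used wherever the
property under test does not need the full model.
"""

import warnings

import numpy as np
import pytest

from alveofem.fem import StiffnessCache
from alveofem.geometry import GeometryParams, build_socket_geometry
from alveofem.fibres import FibreNetworkParams, build_fibre_network
from alveofem.loads import build_load
from alveofem.meshdata import tag_interfaces
from alveofem.variants import make_variant, solve_variant


@pytest.fixture(scope="session")
def small_geometry():
    """A reduced-height single-molar model for fast structural tests."""
    return GeometryParams(corpus_height=15.0, root_length=7.5, crown_height=4.5,
                          seed=1)


@pytest.fixture(scope="session")
def small_model(small_geometry):
    mesh = build_socket_geometry(small_geometry)
    interfaces = tag_interfaces(mesh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fibres = build_fibre_network(mesh, interfaces, FibreNetworkParams(seed=1))
    return mesh, interfaces, fibres, StiffnessCache(mesh)


@pytest.fixture(scope="session")
def default_model():
    """The full default model (the study conditions), built once."""
    from alveofem.verification import default_model as _dm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _dm(seed=1)


@pytest.fixture(scope="session")
def occlusal_solutions(default_model):
    """Occlusal-load solutions of the structure variants plus solid+bulk."""
    mesh, interfaces, fibres, cache = default_model
    case = build_load(mesh, "occlusal")
    sols = {}
    for vid in ("none+structure", "solid+structure", "fibrous+structure", "solid+bulk"):
        v = make_variant(vid, fibres if vid.startswith("fibrous") else None)
        sols[vid] = solve_variant(mesh, v, case, cache)
    return case, sols


@pytest.fixture(scope="session")
def orthodontic_solutions(default_model):
    """Buccolingual orthodontic solutions of the three PDL representations."""
    mesh, interfaces, fibres, cache = default_model
    case = build_load(mesh, "orth_buccolingual")
    sols = {}
    for vid in ("none+structure", "solid+structure", "fibrous+structure"):
        v = make_variant(vid, fibres if vid.startswith("fibrous") else None)
        sols[vid] = solve_variant(mesh, v, case, cache)
    return case, sols
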