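"""Verification benchmarks and headline comparative analyses.

Two layers of checking:

* classic FE verification problems with independent closed-form answers -
  patch tests (linear and quadratic displacement fields), a cantilever-beam
  refinement study, a series-bar compliance check and a brute-force oracle
  for the tension-only active-set iteration;
* the headline comparative quantities of the socket study, recomputed from
  scratch on the default synthetic model: fused-socket orthodontic strain
  level, the excess of cortical surface strain with a PDL over the fused
  model under the occlusal load, and a mesh-convergence measure at five
  cortical-surface sample points.
"""

from __future__ import annotations

import numpy as np

from .analysis import socket_profile, vertical_profile
from .fem import (
    ConstraintSet, Material, StiffnessCache, assemble, fibre_stiffness_matrix,
    nodal_strains_spr, principal_strains, solve_linear, solve_tension_only,
    von_mises_strain,
)
from .fibres import FibreNetworkParams, FibreSet, build_fibre_network
from .geometry import GeometryParams, build_block, build_socket_geometry
from .loads import build_load
from .meshdata import tag_interfaces
from .variants import make_variant, solve_variant

__all__ = [
    "patch_test", "beam_benchmark", "series_bar_check", "active_set_bruteforce",
    "default_model", "socket_strain_fused", "cortical_excess_with_pdl",
    "mesh_convergence", "compute_targets",
]


# --- element-level verification ------------------------------------------------

def _prescribed_field_error(mesh, exact_fn, material=Material(100.0, 0.3)):
    """Solve with the exact field prescribed on the boundary; return max errors."""
    K = assemble(mesh, {"cortical": material})
    nodes = mesh.nodes
    tol = 1e-9
    hi = nodes.max(axis=0)
    on_bnd = np.any((np.abs(nodes) < tol) | (np.abs(nodes - hi) < tol), axis=1)
    bnd = np.flatnonzero(on_bnd)
    exact = exact_fn(nodes)
    cs = ConstraintSet.from_nodes(bnd, [0, 1, 2])
    up = np.zeros(3 * mesh.n_nodes)
    mask = np.zeros(3 * mesh.n_nodes, dtype=bool)
    mask[cs.dofs] = True
    up[mask] = exact.ravel()[mask]
    f = -(K @ up)
    f[mask] = 0.0
    u, _ = solve_linear(K, f, cs, rel_tol=1e-4)
    u_full = (u + up).reshape(-1, 3)
    return float(np.abs(u_full - exact).max())


def patch_test() -> dict:
    """Displacement errors for exactly representable fields on a distorted-free block.

    Quadratic tetrahedra must reproduce linear and quadratic displacement
    fields (with zero body force) to solver precision.
    """
    mesh = build_block(2, 2, 2, (1.0, 1.0, 1.0))

    def linear(x):
        return np.column_stack([0.3 * x[:, 0] + 0.1 * x[:, 1],
                                0.2 * x[:, 1] - 0.05 * x[:, 2],
                                0.15 * x[:, 2] + 0.07 * x[:, 0]])

    def quadratic(x):  # u = (y z, 0, 0): divergence-free shear field
        return np.column_stack([x[:, 1] * x[:, 2], np.zeros(len(x)), np.zeros(len(x))])

    return {
        "linear_field_error": _prescribed_field_error(mesh, linear),
        "quadratic_field_error": _prescribed_field_error(mesh, quadratic),
    }


def beam_benchmark(refinements=(1, 2, 4)) -> dict:
    """Slender cantilever tip deflection vs the Timoshenko closed form."""
    E, nu, P, L, c = 1000.0, 0.3, 1.0, 20.0, 2.0
    I = c * c ** 3 / 12.0
    G = E / (2 * (1 + nu))
    exact = -(P * L ** 3 / (3 * E * I) + P * L / ((5.0 / 6.0) * c * c * G))
    errors = []
    for n in refinements:
        mesh = build_block(10 * n, n, n, (L, c, c))
        K = assemble(mesh, {"cortical": Material(E, nu)})
        cs = ConstraintSet.from_nodes(mesh.set_nodes("x0"), [0, 1, 2])
        tip = mesh.set_nodes("x1")
        f = np.zeros(3 * mesh.n_nodes)
        f[3 * tip + 2] = -P / len(tip)
        u, _ = solve_linear(K, f, cs)
        w = u.reshape(-1, 3)[tip, 2].mean()
        errors.append(abs((w - exact) / exact))
    return {"relative_errors": errors, "exact_mm": exact}


def series_bar_check() -> dict:
    """Two collinear tension-only bars in series vs the closed-form compliance."""
    nodes = np.array([[0.0, 0, 0], [0, 0, 1.0], [0, 0, 2.5]])
    E = np.array([1000.0, 500.0])
    A = np.array([0.02, 0.01])
    L = np.array([1.0, 1.5])
    K = fibre_stiffness_matrix(nodes, np.array([0, 1]), np.array([1, 2]),
                               E, A, np.array([True, True]), 9)
    F = 3.0
    f = np.zeros(9)
    f[8] = F
    cs = ConstraintSet.from_nodes([0], [0, 1, 2]).merge(
        ConstraintSet.from_nodes([1, 2], [0, 1]))
    u, _ = solve_linear(K, f, cs)
    exact = F * (L[0] / (E[0] * A[0]) + L[1] / (E[1] * A[1]))
    return {"fem_mm": float(u[8]), "exact_mm": float(exact),
            "relative_error": float(abs(u[8] - exact) / exact)}


def _toy_fibre_model(n_pairs=4, seed=0):
    """Tiny block with a soft layer bridged by crossed fibres, for oracle tests."""
    mesh = build_block(2, 2, 2, (2.0, 2.0, 2.0))
    z = mesh.nodes[:, 2]
    cent = mesh.nodes[mesh.elements[:, :4]].mean(axis=1)
    soft = cent[:, 2] > 1.0
    from .meshdata import MATERIAL_CODE
    mesh.labels[soft] = MATERIAL_CODE["pdl"]
    lower = np.flatnonzero(np.abs(z - 1.0) < 1e-9)
    upper = np.flatnonzero(np.abs(z - 2.0) < 1e-9)
    rng = np.random.default_rng(seed)
    lo = rng.choice(lower, n_pairs, replace=False)
    bone, root = [], []
    for b in lo:
        # crossed pair: connect to the two nearest upper nodes offset sideways
        d = mesh.nodes[upper] - mesh.nodes[b]
        order = np.argsort(np.abs(d[:, 0] - 0.7) + np.abs(d[:, 1]))
        bone += [b, b]
        root += [int(upper[order[0]])]
        d2 = mesh.nodes[upper] - mesh.nodes[b]
        order2 = np.argsort(np.abs(d2[:, 0] + 0.7) + np.abs(d2[:, 1]))
        root += [int(upper[order2[0]])]
    n = 2 * n_pairs
    fibres = FibreSet(bone_node=np.array(bone), root_node=np.array(root),
                      area=np.full(n, 0.05), group=np.zeros(n, dtype=np.int8),
                      partner=np.arange(n) ^ 1, E=1000.0, nu=0.35, tooth=0)
    mats = {"cortical": Material(1000.0, 0.3), "pdl": Material(0.5, 0.45)}
    K0 = assemble(mesh, mats)
    cs = ConstraintSet.from_nodes(mesh.set_nodes("z0"), [0, 1, 2])
    f = np.zeros(3 * mesh.n_nodes)
    top = mesh.set_nodes("z1")
    f[3 * top + 0] = 0.8 / len(top)    # lateral shear puts half the fibres slack
    f[3 * top + 2] = -0.3 / len(top)
    return mesh, K0, fibres, f, cs


def active_set_bruteforce(n_pairs=4, seed=0) -> dict:
    """Compare the active-set iteration with exhaustive enumeration over 2^n sets.

    The complementarity-consistent active set (active fibres not shortened,
    inactive fibres not elongated) is found by brute force and must match
    the fixed-point iteration's converged set.
    """
    mesh, K0, fibres, f, cs = _toy_fibre_model(n_pairs, seed)
    sol = solve_tension_only(mesh, K0, fibres, f, cs)
    nf = len(fibres)
    nodes = mesh.nodes
    d = nodes[fibres.root_node] - nodes[fibres.bone_node]
    L0 = np.linalg.norm(d, axis=1)
    axis = d / L0[:, None]
    tol = 1e-9 * L0
    consistent = []
    for bits in range(2 ** nf):
        active = np.array([(bits >> i) & 1 for i in range(nf)], dtype=bool)
        Kf = fibre_stiffness_matrix(nodes, fibres.bone_node, fibres.root_node,
                                    fibres.E, fibres.area, active, K0.shape[0])
        u, _ = solve_linear(K0 + Kf, f, cs)
        du = u.reshape(-1, 3)[fibres.root_node] - u.reshape(-1, 3)[fibres.bone_node]
        delta = np.einsum("ij,ij->i", du, axis)
        ok = np.all(delta[active] >= -tol[active]) and np.all(delta[~active] <= tol[~active])
        if ok:
            consistent.append(active)
    return {
        "iterative_set": sol.active,
        "consistent_sets": consistent,
        "match": any(np.array_equal(sol.active, c) for c in consistent),
        "n_consistent": len(consistent),
    }


# --- the default synthetic model ------------------------------------------------

def default_model(seed: int = 1, element_size: float | None = None,
                  geometry: GeometryParams | None = None,
                  fibre_params: FibreNetworkParams | None = None):
    """Build the default single-molar model: mesh, interfaces, fibres, cache."""
    if geometry is None:
        geometry = GeometryParams(seed=seed)
    if element_size is not None:
        from dataclasses import replace
        geometry = replace(geometry, element_size=element_size)
    mesh = build_socket_geometry(geometry)
    interfaces = tag_interfaces(mesh)
    fp = fibre_params if fibre_params is not None else FibreNetworkParams(seed=seed)
    fibres = build_fibre_network(mesh, interfaces, fp)
    return mesh, interfaces, fibres, StiffnessCache(mesh)


# --- headline comparative quantities -------------------------------------------

def socket_strain_fused(seed: int = 1, model=None) -> dict:
    """95th-percentile socket-surface strain magnitude, fused (no-PDL) socket, 1 N.

    Buccolingual orthodontic load on the no-PDL + trabecular-structure
    variant; principal strains sampled on the socket wall at the apex plane
    (buccal and lingual profiles), in microstrain.
    """
    mesh, interfaces, fibres, cache = model if model is not None else default_model(seed)
    case = build_load(mesh, "orth_buccolingual")
    sol = solve_variant(mesh, make_variant("none+structure"), case, cache)
    vals = []
    for side in ("buccal", "lingual"):
        prof = socket_profile(mesh, sol, interfaces, side)
        vals.append(np.percentile(np.abs(prof.e1), 95))
        vals.append(np.percentile(np.abs(prof.e3), 95))
    return {"value": float(max(vals)), "n": mesh.n_elements}


def cortical_excess_with_pdl(seed: int = 1, model=None) -> dict:
    """Median % excess of |e3| with a solid PDL over the fused model, superior third.

    500 N occlusal load; vertical profiles on the outer buccal and lingual
    cortical surfaces; compressive principal strain magnitudes compared
    node-by-node over the superior third of each profile.
    """
    mesh, interfaces, fibres, cache = model if model is not None else default_model(seed)
    case = build_load(mesh, "occlusal")
    sol_solid = solve_variant(mesh, make_variant("solid+structure"), case, cache)
    sol_none = solve_variant(mesh, make_variant("none+structure"), case, cache)
    excesses = []
    for side in ("buccal", "lingual"):
        ps = vertical_profile(mesh, sol_solid, side)
        pn = vertical_profile(mesh, sol_none, side)
        top = ps.positions <= ps.positions.max() / 3.0
        a = np.abs(ps.e3[top])
        b = np.abs(pn.e3[top])
        excesses.append(100.0 * (a - b) / b)
    value = float(np.median(np.concatenate(excesses)))
    return {"value": value, "n": mesh.n_elements}


def _sample_points(mesh):
    W, L, crest = mesh.meta["corpus"]
    yc = mesh.meta["tooth_centres"][mesh.meta["loaded_tooth"]][1]
    za = mesh.meta["z_apex"]
    # five fixed points on the outer buccal cortical surface, in the
    # mid-process band just above the apex plane and offset mesially from
    # the load plane: away from the load-transfer and support
    # concentrations, where the field is smooth enough for a meaningful
    # point-wise convergence audit on a desk-scale mesh
    y = yc - 4.5
    return [(W, y, za + dz) for dz in (1.5, 2.25, 3.0, 3.75, 4.5)]


def _point_measures(mesh, sol, points):
    vals, mask = nodal_strains_spr(mesh, sol.u, ("cortical",))
    sel = np.flatnonzero(mask)
    out = []
    for pt in points:
        i = sel[np.argmin(np.linalg.norm(mesh.nodes[sel] - np.asarray(pt), axis=1))]
        pr = principal_strains(vals[i])[0]
        out.append([pr[0], pr[2], float(von_mises_strain(vals[i])[0])])
    return np.array(out)


def mesh_convergence(seed: int = 1, model=None) -> dict:
    """Max relative change (%) of e1, e3 and von Mises strain at five surface points.

    Solid-PDL + bulk variant under the occlusal load, solved on the default
    mesh and on a mesh with the target element size halved; strain measures
    sampled by nearest-node lookup at five fixed cortical-surface points.
    """
    if model is not None:
        mesh, interfaces, fibres, cache = model
        geometry = mesh.meta["params"]
    else:
        geometry = GeometryParams(seed=seed)
        mesh, interfaces, fibres, cache = default_model(seed, geometry=geometry)
    points = _sample_points(mesh)
    case = build_load(mesh, "occlusal")
    base = _point_measures(mesh, solve_variant(mesh, make_variant("solid+bulk"), case, cache), points)

    from dataclasses import replace
    fine_geom = replace(geometry, element_size=geometry.element_size / 2.0)
    mesh_f = build_socket_geometry(fine_geom)
    cache_f = StiffnessCache(mesh_f)
    case_f = build_load(mesh_f, "occlusal")
    fine = _point_measures(mesh_f, solve_variant(mesh_f, make_variant("solid+bulk"), case_f, cache_f), points)
    rel = np.abs(base - fine) / np.abs(fine)
    return {"value": float(rel.max() * 100.0), "n": mesh_f.n_elements,
            "per_point_percent": (rel * 100.0).tolist()}


def compute_targets(seed: int = 1) -> dict:
    """Recompute the three headline quantities from scratch on the default model."""
    model = default_model(seed)
    t1 = socket_strain_fused(seed, model)
    t4 = cortical_excess_with_pdl(seed, model)
    t5 = mesh_convergence(seed, model)
    return {
        "t1": {"value": t1["value"], "n": t1["n"]},
        "t4": {"value": t4["value"], "n": t4["n"]},
        "t5": {"value": t5["value"], "n": t5["n"]},
    }
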