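"""Small-strain linear-elastic finite-element core.

Ten-node tetrahedra (quadratic displacement, straight-sided, 4-point Gauss
quadrature — exact for the constant-Jacobian quadratic element) carry the
continuum; two-node tension-only bar elements carry the PDL fibres.  The
tension-only state is resolved by a fixed-point active-set iteration.

Voigt order is (xx, yy, zz, xy, yz, xz) with engineering shear strains.
Units: mm, N, MPa; strains dimensionless (reported downstream in
microstrain, 1 us = 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshdata import MATERIALS, LabeledMesh

__all__ = [
    "Material", "ConstraintSet", "Solution",
    "elasticity_matrix", "tet10_stiffness", "link_stiffness",
    "assemble", "fibre_stiffness_matrix", "solve_linear", "solve_tension_only",
    "recover_strains", "nodal_strains", "nodal_strains_spr",
    "principal_strains", "von_mises_strain",
]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus E (MPa), Poisson ratio nu."""

    E: float
    nu: float = 0.3

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5)")


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic Hooke operator in Voigt notation (engineering shears)."""
    E, nu = material.E, material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


# --- tet10 element ----------------------------------------------------------

_GA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_GB = (5.0 - np.sqrt(5.0)) / 20.0
#: 4-point Gauss rule in natural coordinates (xi, eta, zeta); weight V/4 each
GAUSS4 = np.array([
    (_GA, _GB, _GB), (_GB, _GA, _GB), (_GB, _GB, _GA), (_GB, _GB, _GB),
])


def _shape_gradients_natural(points: np.ndarray) -> np.ndarray:
    """dN/d(xi,eta,zeta) of the 10 tet10 shape functions, shape (npts, 10, 3)."""
    pts = np.atleast_2d(points)
    out = np.zeros((len(pts), 10, 3))
    for q, (xi, eta, zeta) in enumerate(pts):
        L = np.array([1 - xi - eta - zeta, xi, eta, zeta])
        dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        for i in range(4):
            out[q, i] = (4 * L[i] - 1) * dL[i]
        for m, (a, b) in enumerate(((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))):
            out[q, 4 + m] = 4 * (L[a] * dL[b] + L[b] * dL[a])
    return out


_DN4 = _shape_gradients_natural(GAUSS4)  # (4, 10, 3)


def _b_matrices(coords10: np.ndarray, dn_nat: np.ndarray):
    """Strain-displacement matrices at quadrature points for a batch of tet10s.

    coords10: (n, 10, 3).  Returns (B, detJ) with B of shape (n, nq, 6, 30).
    """
    p0 = coords10[:, 0]
    J = np.stack([coords10[:, 1] - p0, coords10[:, 2] - p0, coords10[:, 3] - p0], axis=2)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.flatnonzero(detJ <= 0)[:5]
        raise ValueError(f"non-positive Jacobian in elements {bad.tolist()} of batch")
    invJ = np.linalg.inv(J)
    # global gradients (n, nq, 10, 3)
    grad = np.einsum("qia,nab->nqib", dn_nat, invJ)
    n, nq = grad.shape[:2]
    B = np.zeros((n, nq, 6, 30))
    gx, gy, gz = grad[..., 0], grad[..., 1], grad[..., 2]
    cols = 3 * np.arange(10)
    B[..., 0, cols + 0] = gx
    B[..., 1, cols + 1] = gy
    B[..., 2, cols + 2] = gz
    B[..., 3, cols + 0] = gy
    B[..., 3, cols + 1] = gx
    B[..., 4, cols + 1] = gz
    B[..., 4, cols + 2] = gy
    B[..., 5, cols + 0] = gz
    B[..., 5, cols + 2] = gx
    return B, detJ


def tet10_stiffness(coords: np.ndarray, D: np.ndarray) -> np.ndarray:
    """30x30 stiffness of one 10-node tetrahedron (4-point Gauss).

    Raises ``ValueError`` for a non-positive Jacobian (degenerate or inverted
    element).
    """
    coords = np.asarray(coords, dtype=float).reshape(1, 10, 3)
    B, detJ = _b_matrices(coords, _DN4)
    if detJ[0] <= 0:
        raise ValueError(f"non-positive Jacobian ({detJ[0]:.3e}); degenerate tetrahedron")
    w = detJ[0] / 24.0  # V/4 per point
    K = np.einsum("qki,kl,qlj->ij", B[0], D, B[0]) * w
    return 0.5 * (K + K.T)


def link_stiffness(xa: np.ndarray, xb: np.ndarray, E: float, area: float,
                   active: bool = True):
    """6x6 stiffness of a two-node axial bar, plus its axis and rest length.

    Tension-only bars contribute a zero matrix when inactive.
    """
    xa, xb = np.asarray(xa, float), np.asarray(xb, float)
    L0 = float(np.linalg.norm(xb - xa))
    if L0 <= 0:
        raise ValueError("bar element has coincident endpoints")
    n = (xb - xa) / L0
    if not active:
        return np.zeros((6, 6)), n, L0
    k = E * area / L0
    nnT = k * np.outer(n, n)
    K = np.block([[nnT, -nnT], [-nnT, nnT]])
    return K, n, L0


# --- assembly ---------------------------------------------------------------


def _element_dofs(conn: np.ndarray) -> np.ndarray:
    """(n, 30) global DOF indices, interleaved (x0,y0,z0,x1,...)."""
    return (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(len(conn), -1)


def _assemble_elements(mesh: LabeledMesh, idx: np.ndarray, D: np.ndarray,
                       chunk: int) -> sp.csr_matrix:
    ndof = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for start in range(0, len(idx), chunk):
        e = idx[start : start + chunk]
        conn = mesh.elements[e]
        coords = mesh.nodes[conn]
        B, detJ = _b_matrices(coords, _DN4)
        if np.any(detJ <= 0):
            bad = e[detJ <= 0][:5]
            raise ValueError(f"non-positive Jacobian in elements {bad.tolist()}")
        Ke = np.einsum("nqki,kl,nqlj->nij", B, D, B) * (detJ / 24.0)[:, None, None]
        dofs = _element_dofs(conn)
        rows.append(np.repeat(dofs, 30, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 30)).ravel())
        vals.append(Ke.ravel())
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()


def _check_materials(mesh: LabeledMesh, materials: dict[str, Material]):
    present = {MATERIALS[c] for c in np.unique(mesh.labels)}
    missing = present - set(materials)
    if missing:
        raise ValueError(f"no material assigned to label(s): {sorted(missing)}")
    return present


def assemble(mesh: LabeledMesh, materials: dict[str, Material],
             fibre_matrix: sp.spmatrix | None = None,
             chunk: int = 4000) -> sp.csr_matrix:
    """Global stiffness matrix from the labelled mesh and a material map.

    ``materials`` must map every material label present in the mesh to a
    :class:`Material`.  Assembly is order-independent (pure summation).
    """
    present = _check_materials(mesh, materials)
    K = None
    for name in sorted(present):
        D = elasticity_matrix(materials[name])
        Kl = _assemble_elements(mesh, mesh.elements_of(name), D, chunk)
        K = Kl if K is None else K + Kl
    if fibre_matrix is not None:
        K = K + fibre_matrix
    return K.tocsr()


class StiffnessCache:
    """Reusable per-material stiffness blocks for one mesh.

    The isotropic Hooke operator is linear in E at fixed Poisson ratio, so
    the global matrix of any material assignment is a weighted sum of
    unit-modulus blocks, one per (label, nu).  This makes solving many
    material variants of the same mesh (and scalar modulus optimisation)
    cheap after a one-time assembly.
    """

    def __init__(self, mesh: LabeledMesh, chunk: int = 4000):
        self.mesh = mesh
        self.chunk = chunk
        self._unit: dict[tuple[str, float], sp.csr_matrix] = {}

    def matrix(self, materials: dict[str, Material]) -> sp.csr_matrix:
        present = _check_materials(self.mesh, materials)
        K = None
        for name in sorted(present):
            mat = materials[name]
            key = (name, round(mat.nu, 12))
            if key not in self._unit:
                D = elasticity_matrix(Material(1.0, mat.nu))
                self._unit[key] = _assemble_elements(
                    self.mesh, self.mesh.elements_of(name), D, self.chunk)
            Kl = self._unit[key] * mat.E
            K = Kl if K is None else K + Kl
        return K.tocsr()


def fibre_stiffness_matrix(nodes: np.ndarray, node_a: np.ndarray, node_b: np.ndarray,
                           E: np.ndarray, area: np.ndarray,
                           active: np.ndarray, ndof: int) -> sp.csr_matrix:
    """Sparse stiffness of a set of bar elements (only active ones contribute)."""
    sel = np.flatnonzero(active)
    if len(sel) == 0:
        return sp.csr_matrix((ndof, ndof))
    a, b = node_a[sel], node_b[sel]
    d = nodes[b] - nodes[a]
    L0 = np.linalg.norm(d, axis=1)
    n = d / L0[:, None]
    k = np.asarray(E)[sel] if np.ndim(E) else float(E)
    k = k * np.asarray(area)[sel] / L0
    nnT = k[:, None, None] * (n[:, :, None] * n[:, None, :])
    K6 = np.empty((len(sel), 6, 6))
    K6[:, :3, :3] = nnT
    K6[:, 3:, 3:] = nnT
    K6[:, :3, 3:] = -nnT
    K6[:, 3:, :3] = -nnT
    dofs = np.concatenate([3 * a[:, None] + np.arange(3), 3 * b[:, None] + np.arange(3)], axis=1)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    return sp.coo_matrix((K6.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()


# --- constraints and solving -------------------------------------------------


@dataclass
class ConstraintSet:
    """Prescribed (zero-valued) degrees of freedom."""

    dofs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @classmethod
    def from_nodes(cls, nodes: np.ndarray, components) -> "ConstraintSet":
        comps = np.atleast_1d(np.asarray(components, dtype=np.int64))
        dofs = (3 * np.asarray(nodes, dtype=np.int64)[:, None] + comps[None, :]).ravel()
        return cls(np.unique(dofs))

    def merge(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(np.union1d(self.dofs, other.dofs))


class _RigidAggregationPreconditioner:
    """Two-level preconditioner for 3-D elasticity (smoothed rigid-body aggregation).

    Nodes are aggregated into geometric boxes; the tentative prolongation
    carries the six rigid-body modes of each aggregate (the near-nullspace of
    elasticity), smoothed by one damped-Jacobi step.  The Galerkin coarse
    operator is factorised directly; the fine level is smoothed with damped
    Jacobi.  Applied as a symmetric V-cycle inside conjugate gradients, this
    tolerates the extreme material contrasts of the socket models (cortical
    bone vs PDL matrix vs trabecular pore filling).
    """

    def __init__(self, Kff: sp.csr_matrix, node_xyz: np.ndarray,
                 free_dofs: np.ndarray, box: float, n_smooth: int = 2):
        self.K = Kff
        d = Kff.diagonal()
        d[d <= 0] = 1.0
        self.dinv = 1.0 / d
        # power iteration for lambda_max(D^-1 K)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(Kff.shape[0])
        lam = 1.0
        for _ in range(20):
            y = self.dinv * (Kff @ x)
            lam = np.linalg.norm(y)
            x = y / lam
        self.omega = 1.0 / (1.1 * lam)
        # Chebyshev smoothing interval on D^-1 K
        self.lmax = 1.1 * lam * 1.05
        self.lmin = self.lmax / 30.0
        self.n_smooth = n_smooth
        P = self._tentative(node_xyz, box)[free_dofs]
        # one smoothing step spreads the aggregate modes and sharpens the coarse space
        P = (P - sp.diags(self.omega * self.dinv) @ (Kff @ P)).tocsr()
        self.P = P
        Kc = (P.T @ Kff @ P).tocsc()
        Kc = Kc + sp.eye(Kc.shape[0]) * (1e-12 * abs(Kc.diagonal()).max())
        self.coarse = spla.splu(Kc, permc_spec="MMD_AT_PLUS_A")

    @staticmethod
    def _tentative(xyz: np.ndarray, box: float) -> sp.csr_matrix:
        keys = np.floor(xyz / box).astype(np.int64)
        _, agg = np.unique(keys, axis=0, return_inverse=True)
        n_agg = agg.max() + 1
        # centroids per aggregate
        cx = np.zeros((n_agg, 3))
        cnt = np.zeros(n_agg)
        np.add.at(cx, agg, xyz)
        np.add.at(cnt, agg, 1.0)
        cx /= cnt[:, None]
        rel = xyz - cx[agg]
        n = len(xyz)
        # per node a 3x6 block: [I | -skew(rel)]
        blocks = np.zeros((n, 3, 6))
        blocks[:, 0, 0] = blocks[:, 1, 1] = blocks[:, 2, 2] = 1.0
        rx, ry, rz = rel[:, 0], rel[:, 1], rel[:, 2]
        blocks[:, 0, 4] = rz
        blocks[:, 0, 5] = -ry
        blocks[:, 1, 3] = -rz
        blocks[:, 1, 5] = rx
        blocks[:, 2, 3] = ry
        blocks[:, 2, 4] = -rx
        rows = np.repeat(np.arange(3 * n).reshape(n, 3), 6, axis=1).reshape(n, 3, 6)
        cols = (6 * agg)[:, None, None] + np.arange(6)[None, None, :]
        cols = np.broadcast_to(cols, (n, 3, 6))
        P = sp.coo_matrix((blocks.ravel(), (rows.ravel(), cols.ravel())),
                          shape=(3 * n, 6 * n_agg)).tocsr()
        return P

    def _smooth(self, x, r, degree=3):
        # Chebyshev iteration for the Jacobi-preconditioned operator
        theta = (self.lmax + self.lmin) / 2.0
        delta = (self.lmax - self.lmin) / 2.0
        sigma = theta / delta
        rho = 1.0 / sigma
        d = self.dinv * (r - self.K @ x) / theta
        x = x + d
        for _ in range(degree - 1):
            rho_new = 1.0 / (2.0 * sigma - rho)
            res = self.dinv * (r - self.K @ x)
            d = rho_new * rho * d + (2.0 * rho_new / delta) * res
            rho = rho_new
            x = x + d
        return x

    def apply(self, r: np.ndarray) -> np.ndarray:
        x = self._smooth(np.zeros_like(r), r)
        rc = self.P.T @ (r - self.K @ x)
        x = x + self.P @ self.coarse.solve(rc)
        return self._smooth(x, r)


#: systems at or below this size go straight to the sparse direct solver
DIRECT_SOLVE_MAX_DOF = 20000


def solve_linear(K: sp.spmatrix, f: np.ndarray, constraints: ConstraintSet,
                 rel_tol: float = 1e-6, node_xyz: np.ndarray | None = None,
                 method: str = "auto", cg_tol: float = 1e-9,
                 agg_box: float | None = None,
                 precond: "_RigidAggregationPreconditioner | None" = None,
                 x0: np.ndarray | None = None):
    """Solve K u = f with zero-valued constrained DOFs (row/column elimination).

    Small systems are factorised directly (SuperLU); larger ones use
    conjugate gradients with a two-level rigid-body-aggregation
    preconditioner, which needs the nodal coordinates (``node_xyz``).

    Returns ``(u, reactions)`` where ``reactions`` is the residual K u - f,
    nonzero only on constrained DOFs.  Verifies the free-DOF residual
    against ``rel_tol`` * ||f||.
    """
    ndof = K.shape[0]
    fixed = np.zeros(ndof, dtype=bool)
    fixed[constraints.dofs] = True
    free = ~fixed
    Kff = K[free][:, free].tocsr()
    nfree = Kff.shape[0]
    if method == "auto":
        method = "direct" if (nfree <= DIRECT_SOLVE_MAX_DOF or node_xyz is None) else "amg_cg"
    try:
        if method == "direct":
            lu = spla.splu(Kff.tocsc(), permc_spec="MMD_AT_PLUS_A")
            uf = lu.solve(f[free])
        else:
            if precond is None:
                if agg_box is None:
                    # aim for a coarse space of at most ~9000 DOFs
                    span = np.ptp(node_xyz, axis=0)
                    vol = float(np.prod(span))
                    agg_box = max((vol / (9000 / 6.0)) ** (1.0 / 3.0), 1e-3)
                precond = _RigidAggregationPreconditioner(Kff, node_xyz, free, box=agg_box)
            op = spla.LinearOperator(Kff.shape, precond.apply)
            uf, info = spla.cg(Kff, f[free], rtol=cg_tol, atol=0.0,
                               maxiter=2000, M=op,
                               x0=None if x0 is None else x0[free])
            if info != 0:
                raise ValueError(
                    f"preconditioned CG failed to converge (info={info}); "
                    "system may be ill-posed or under-constrained")
    except RuntimeError as exc:
        raise ValueError(
            "singular stiffness matrix - are all rigid-body modes constrained?"
        ) from exc
    if not np.all(np.isfinite(uf)):
        raise ValueError(
            "singular stiffness matrix - are all rigid-body modes constrained?"
        )
    u = np.zeros(ndof)
    u[free] = uf
    residual = K @ u - f
    fnorm = np.linalg.norm(f)
    if fnorm > 0 and np.linalg.norm(residual[free]) > rel_tol * fnorm:
        raise ValueError(
            f"solver residual {np.linalg.norm(residual[free]):.2e} exceeds "
            f"{rel_tol:.0e} * ||f||; system may be near-singular"
        )
    reactions = np.where(fixed, residual, 0.0)
    return u, reactions


@dataclass
class Solution:
    """Converged FE solution for one variant under one load case."""

    u: np.ndarray                 # (n_nodes, 3) displacements, mm
    reactions: np.ndarray         # (ndof,) reaction forces on constrained DOFs, N
    elem_strain: np.ndarray       # (n_elem, 6) Voigt engineering strains
    f: np.ndarray                 # applied load vector (ndof,), N
    active: np.ndarray | None = None       # per-fibre active flags
    elongations: np.ndarray | None = None  # per-fibre axial elongation, mm
    iterations: list = field(default_factory=list)


def solve_tension_only(mesh: LabeledMesh, K0: sp.csr_matrix, fibres,
                       f: np.ndarray, constraints: ConstraintSet,
                       delta_tol: float = 1e-12, max_iter: int = 50) -> Solution:
    """Active-set fixed-point iteration for tension-only fibre elements.

    All fibres start active; after each linear solve, fibres whose axial
    elongation is below ``-delta_tol * L0`` are deactivated and fibres
    elongated beyond ``+delta_tol * L0`` are reactivated, until the active
    set is unchanged.  On detected cycling the visited set with the smallest
    total complementarity violation is kept.
    """
    ndof = 3 * mesh.n_nodes
    nodes = mesh.nodes
    a, b = fibres.bone_node, fibres.root_node
    d = nodes[b] - nodes[a]
    L0 = np.linalg.norm(d, axis=1)
    axis = d / L0[:, None]
    tol = delta_tol * L0

    state = {"precond": None, "u": None}

    def solve_with(active):
        Kf = fibre_stiffness_matrix(nodes, a, b, fibres.E, fibres.area, active, ndof)
        K = K0 + Kf
        if state["precond"] is None and 3 * len(nodes) > DIRECT_SOLVE_MAX_DOF:
            # one preconditioner (built for the all-active system) serves the
            # whole active-set iteration; CG warm-starts from the last solve
            fixed = np.zeros(ndof, dtype=bool)
            fixed[constraints.dofs] = True
            span = np.ptp(nodes, axis=0)
            box = max((float(np.prod(span)) / 1500.0) ** (1.0 / 3.0), 1e-3)
            state["precond"] = _RigidAggregationPreconditioner(
                K[~fixed][:, ~fixed].tocsr(), nodes, ~fixed, box=box)
        u, reactions = solve_linear(K, f, constraints, node_xyz=nodes,
                                    precond=state["precond"], x0=state["u"])
        state["u"] = u
        du = u.reshape(-1, 3)[b] - u.reshape(-1, 3)[a]
        delta = np.einsum("ij,ij->i", du, axis)
        return u, reactions, delta

    def violation(active, delta):
        v = np.where(active, np.maximum(-delta - tol, 0.0), np.maximum(delta - tol, 0.0))
        return float(v.sum())

    active = np.ones(len(L0), dtype=bool)
    seen: dict[bytes, int] = {}
    log = []
    best = None
    for it in range(max_iter):
        key = np.packbits(active).tobytes()
        u, reactions, delta = solve_with(active)
        viol = violation(active, delta)
        log.append({"iteration": it, "n_active": int(active.sum()), "violation": viol})
        if best is None or viol < best[0]:
            best = (viol, active.copy(), u, reactions, delta)
        new_active = active.copy()
        new_active[delta < -tol] = False
        new_active[delta > tol] = True
        if np.array_equal(new_active, active):
            break
        if key in seen:  # cycle: keep the best visited set
            log.append({"iteration": it, "note": "cycle detected; keeping best set"})
            _, active, u, reactions, delta = best
            break
        seen[key] = it
        active = new_active
    else:
        osc = np.flatnonzero(active != new_active)
        raise RuntimeError(
            f"tension-only iteration did not converge in {max_iter} iterations; "
            f"oscillating fibres: {osc[:20].tolist()}"
        )
    u2 = u.reshape(-1, 3)
    sol = Solution(u=u2, reactions=reactions, elem_strain=recover_strains(mesh, u2),
                   f=f, active=active, elongations=delta, iterations=log)
    return sol


# --- strain recovery ----------------------------------------------------------


def recover_strains(mesh: LabeledMesh, u: np.ndarray, chunk: int = 4000) -> np.ndarray:
    """Per-element strain tensors (Voigt), averaged over the quadrature points."""
    ue = u.reshape(-1, 3)
    out = np.empty((mesh.n_elements, 6))
    for start in range(0, mesh.n_elements, chunk):
        conn = mesh.elements[start : start + chunk]
        coords = mesh.nodes[conn]
        B, _ = _b_matrices(coords, _DN4)
        ue_flat = ue[conn].reshape(len(conn), 30)
        eps = np.einsum("nqij,nj->nqi", B, ue_flat)
        out[start : start + len(conn)] = eps.mean(axis=1)
    return out


def nodal_strains(mesh: LabeledMesh, elem_strain: np.ndarray,
                  labels: tuple[str, ...] = ("cortical", "trabecular_bone")):
    """Volume-weighted nodal averaging over adjacent elements of the given materials.

    Averaging never crosses into other materials, so bone-surface values are
    not blurred by the much softer PDL.  Returns ``(values, mask)`` where
    ``mask`` marks nodes adjacent to at least one selected element.
    """
    idx = mesh.elements_of(*labels)
    vols = np.abs(np.asarray(mesh.volumes()))[idx]
    conn = mesh.elements[idx]
    num = np.zeros((mesh.n_nodes, 6))
    den = np.zeros(mesh.n_nodes)
    w = vols[:, None] * elem_strain[idx]
    for k in range(10):
        np.add.at(num, conn[:, k], w)
        np.add.at(den, conn[:, k], vols)
    mask = den > 0
    num[mask] /= den[mask, None]
    return num, mask


def nodal_strains_spr(mesh: LabeledMesh, u: np.ndarray,
                      labels: tuple[str, ...] = ("cortical", "trabecular_bone"),
                      chunk: int = 4000):
    """Superconvergent patch recovery of nodal strains (same-material patches).

    For every node adjacent to elements of the selected materials, a linear
    polynomial is fitted by least squares to the quadrature-point strains of
    those elements and evaluated at the node (Zienkiewicz-Zhu patch
    recovery).  This converges one order faster than volume averaging at
    points where the strain field is smooth, and is what the profile and
    point-sampling operations use.  Returns ``(values, mask)``.
    """
    ue = u.reshape(-1, 3)
    idx = mesh.elements_of(*labels)
    n_nodes = mesh.n_nodes
    AtA = np.zeros((n_nodes, 4, 4))
    Atb = np.zeros((n_nodes, 4, 6))
    bary = np.column_stack([1.0 - GAUSS4.sum(axis=1), GAUSS4])  # (4 pts, 4 corners)
    for start in range(0, len(idx), chunk):
        e = idx[start : start + chunk]
        conn = mesh.elements[e]
        coords = mesh.nodes[conn]
        B, _ = _b_matrices(coords, _DN4)
        eps_g = np.einsum("nqij,nj->nqi", B, ue[conn].reshape(len(conn), 30))
        xg = np.einsum("qc,ncd->nqd", bary, coords[:, :4])  # gauss positions
        for a in range(10):
            nid = conn[:, a]
            d = xg - mesh.nodes[nid][:, None, :]
            phi = np.concatenate([np.ones(d.shape[:2] + (1,)), d], axis=2)  # (n,q,4)
            np.add.at(AtA, nid, np.einsum("nqi,nqj->nij", phi, phi))
            np.add.at(Atb, nid, np.einsum("nqi,nqk->nik", phi, eps_g))
    mask = AtA[:, 0, 0] > 0
    vals = np.zeros((n_nodes, 6))
    sel = np.flatnonzero(mask)
    A = AtA[sel]
    ridge = 1e-10 * np.trace(A, axis1=1, axis2=2)
    A = A + ridge[:, None, None] * np.eye(4)
    try:
        sol = np.linalg.solve(A, Atb[sel])
        vals[sel] = sol[:, 0, :]
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A.reshape(-1, 4), Atb[sel].reshape(-1, 6), rcond=None)
        vals[sel] = sol[:6]
    # guard: fall back to plain averaging where the local fit is unstable
    bad = sel[~np.isfinite(vals[sel]).all(axis=1)]
    if len(bad):
        avg, _ = nodal_strains(mesh, recover_strains(mesh, ue), labels)
        vals[bad] = avg[bad]
    return vals, mask


def _voigt_to_tensor(eps: np.ndarray) -> np.ndarray:
    eps = np.atleast_2d(eps)
    T = np.zeros(eps.shape[:-1] + (3, 3))
    T[..., 0, 0] = eps[..., 0]
    T[..., 1, 1] = eps[..., 1]
    T[..., 2, 2] = eps[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = eps[..., 3] / 2.0
    T[..., 1, 2] = T[..., 2, 1] = eps[..., 4] / 2.0
    T[..., 0, 2] = T[..., 2, 0] = eps[..., 5] / 2.0
    return T


def principal_strains(eps: np.ndarray) -> np.ndarray:
    """Principal strains sorted descending (eps1 >= eps2 >= eps3)."""
    vals = np.linalg.eigvalsh(_voigt_to_tensor(eps))
    return vals[..., ::-1]


def von_mises_strain(eps: np.ndarray) -> np.ndarray:
    """Effective (von Mises) strain sqrt(2/3 e:e) of the deviatoric strain e."""
    T = _voigt_to_tensor(eps)
    tr = np.trace(T, axis1=-2, axis2=-1)
    dev = T - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(2.0 / 3.0 * np.einsum("...ij,...ij->...", dev, dev))
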