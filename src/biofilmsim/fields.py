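"""Evolution of the biofilm phase field and the nutrient concentration.

Both fields are nodal, trilinearly interpolated, and advanced with
backward Euler on the normalized-time evolution equations

    dphi/dt = beta * lap(phi) + k_alpha * alpha
              - (r c / (k + c)) * (grad(phi) . grad(c)) / |grad(c)|
    dc/dt   = d * lap(c) - g * phi

with zero-flux boundaries; the nutrient source is a Dirichlet set
(c = 1) defined by the boundary value problem.  The directional growth
term is the Monod rate times the cosine between the two field gradients
("orientation"), weighted by |grad(phi)| so that growth is confined to
the biofilm/void interface.  Integration uses 2x2x2 Gauss quadrature on
the regular bricks; assembly covers active elements only.

Both fields are normalized concentrations, so each completed substep is
clamped onto [0, 1] (nutrients are exhausted to exactly zero inside a
consuming biofilm; the linear sink alone would overshoot).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh, BVPSpec

logger = logging.getLogger("biofilmsim")

__all__ = [
    "MaterialParams",
    "LinearSolver",
    "CachedKrylovSolver",
    "assemble_c_system",
    "assemble_phi_system",
    "FieldState",
    "FieldOperators",
    "monod_rate",
    "orientation",
    "growth_source",
    "step_c",
    "step_phi",
    "project_bounds",
    "init_state",
    "SolverFailure",
]


class SolverFailure(RuntimeError):
    """A linear or nonlinear solve failed; the substep should be bisected."""


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass
class MaterialParams:
    """Normalized model constants.

    The defaults are the baseline simulation parameters: shear modulus
    ``mu`` (Pa, equivalent to E = 10 Pa at nu = 0.49), nutrient
    diffusivity ``d`` and phase-field regularization ``beta``
    (um^2 per unit normalized time), growth factor ``k_alpha``,
    consumption parameter ``g`` and Monod growth parameter ``r`` (all
    per unit normalized time), and the dimensionless half-velocity
    constant ``k``.  ``d``, ``beta``, ``k_alpha``, ``g`` and ``r`` are
    the viscosity-normalized values (already divided by their eta), so
    the eta fields are retained only for completeness.

    ``eps_grad`` is the gradient-norm threshold below which the
    orientation term is treated as exactly zero; ``stiffness_floor`` is
    the ersatz stiffness added to phi^2 in the mechanical assembly so
    the void keeps a (tiny) definite stiffness.

    ``c_shutoff`` regularizes the consumption sink near exhaustion: the
    sink is ``g phi c/(c + c_shutoff)``, i.e. the nominal rate ``g phi``
    wherever nutrients remain (c >> c_shutoff) and zero where they are
    gone.  The bare linear sink keeps consuming at c = 0 and, through
    the quasi-steady diffusion solve, drags the whole concentration
    field to unphysical negative values that clamping alone cannot
    repair; set ``c_shutoff = 0`` to recover the bare law.
    """

    mu: float = 3.3557
    d: float = 1e10
    beta: float = 2.0
    k_alpha: float = 1e-3
    k: float = 1.0
    g: float = 1e8
    r: float = 100.0
    eta_phi: float = 1e-10
    eta_c: float = 1e-10
    eta_alpha: float = 1e-10
    eps_grad: float = 1e-8
    stiffness_floor: float = 1e-3
    c_shutoff: float = 0.01

    def __post_init__(self) -> None:
        for name in ("mu", "d", "beta", "k_alpha", "g", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k <= 0:
            raise ValueError("half-velocity constant k must be positive")
        if self.eps_grad <= 0:
            raise ValueError("eps_grad must be positive")

    @classmethod
    def maze_defaults(cls, **overrides) -> "MaterialParams":
        """Large-domain parameter set used for the maze geometry."""
        base = dict(d=1e13, beta=10.0, k_alpha=1e-6, r=200.0)
        base.update(overrides)
        return cls(**base)


@dataclass
class FieldState:
    """All unknowns at one time instant.

    ``phi`` and ``c`` are nodal and dimensionless in [0, 1]; ``u`` is the
    nodal displacement (um); ``p`` the per-element hydrostatic stress
    (Pa, tension positive); ``alpha`` the local expansion parameter at
    the 8 Gauss points of every element (zero and frozen on inactive
    elements).
    """

    t_star: float
    phi: np.ndarray
    c: np.ndarray
    u: np.ndarray
    p: np.ndarray
    alpha: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(
            self.t_star, self.phi.copy(), self.c.copy(), self.u.copy(),
            self.p.copy(), self.alpha.copy(),
        )


def init_state(mesh: Mesh, bvp: BVPSpec) -> FieldState:
    """Initial condition: phi = 1 on the colony set, c = 1 on the source."""
    phi = np.zeros(mesh.n_nodes)
    phi[mesh.node_sets[bvp.phi_init_set]] = 1.0
    c = np.zeros(mesh.n_nodes)
    name, value = bvp.c_dirichlet
    c[mesh.node_sets[name]] = value
    return FieldState(
        0.0, phi, c, np.zeros((mesh.n_nodes, 3)),
        np.zeros(mesh.n_elements), np.zeros((mesh.n_elements, 8)),
    )


# ---------------------------------------------------------------------------
# pointwise model functions
# ---------------------------------------------------------------------------

def monod_rate(c, r: float, k: float):
    """Monod growth speed r*c/(k+c); saturates at r for large c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative nutrient concentration")
    return r * c / (k + c)


def orientation(grad_phi, grad_c, eps_grad: float = 1e-8):
    """Cosine between the two gradients; 0 when either is degenerate."""
    grad_phi = np.asarray(grad_phi, dtype=float)
    grad_c = np.asarray(grad_c, dtype=float)
    np_ = np.linalg.norm(grad_phi, axis=-1)
    nc = np.linalg.norm(grad_c, axis=-1)
    dot = np.sum(grad_phi * grad_c, axis=-1)
    good = (np_ >= eps_grad) & (nc >= eps_grad)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(good, dot / np.where(good, np_ * nc, 1.0), 0.0)
    return out if out.ndim else float(out)


def growth_source(grad_phi, c, grad_c, params: MaterialParams):
    """Interface growth term |grad phi| * monod(c) * orientation.

    Equals ``monod(c) * (grad_phi . grad_c)/|grad_c|``; it enters the
    phi residual with a plus sign, so the phase field *gains* where the
    two gradients are anti-parallel (the interface facing the source).
    Zero where the nutrient gradient is below ``eps_grad``.
    """
    grad_phi = np.asarray(grad_phi, dtype=float)
    grad_c = np.asarray(grad_c, dtype=float)
    nc = np.linalg.norm(grad_c, axis=-1)
    good = nc >= params.eps_grad
    dot = np.sum(grad_phi * grad_c, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(good, monod_rate(c, params.r, params.k) * dot / np.where(good, nc, 1.0), 0.0)
    return out if out.ndim else float(out)


def project_bounds(field_values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Pointwise clamp onto [lo, hi] (idempotent)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    return np.clip(field_values, lo, hi)


# ---------------------------------------------------------------------------
# finite element operators
# ---------------------------------------------------------------------------

_GPTS = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_LOCAL = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)


def gauss_data(spacing: Tuple[float, float, float]):
    """Shape functions and reference-coordinate gradients at the 8 Gauss
    points of a regular brick; identical for every element of the grid.

    Returns ``(N, dN, w)`` with N (8gp, 8nodes), dN (8gp, 8nodes, 3) in
    1/um, and the scalar quadrature weight w (um^3 per Gauss point).
    """
    hx, hy, hz = spacing
    pts = [(x, y, z) for z in _GPTS for y in _GPTS for x in _GPTS]
    N = np.empty((8, 8))
    dN = np.empty((8, 8, 3))
    for g, (xi, et, ze) in enumerate(pts):
        for a, (sx, sy, sz) in enumerate(_LOCAL):
            N[g, a] = 0.125 * (1 + sx * xi) * (1 + sy * et) * (1 + sz * ze)
            dN[g, a] = 0.125 * np.array([
                sx * (1 + sy * et) * (1 + sz * ze) * 2.0 / hx,
                (1 + sx * xi) * sy * (1 + sz * ze) * 2.0 / hy,
                (1 + sx * xi) * (1 + sy * et) * sz * 2.0 / hz,
            ])
    w = hx * hy * hz / 8.0
    return N, dN, w


class FieldOperators:
    """Cached assembled operators for one mesh.

    Holds the consistent mass matrix ``M`` and the Laplacian stiffness
    ``K`` (both over active elements, zero-flux natural boundaries), the
    Gauss-point tabulation, and the factorization of the nutrient system
    (constant in time, so factorized once per time-step size).
    """

    def __init__(self, mesh: Mesh, lumped_mass: bool = False):
        self.mesh = mesh
        self.N, self.dN, self.w = gauss_data(mesh.spacing)
        self.conn = mesh.element_conn[mesh.active_mask]
        n = mesh.n_nodes
        Me = self.w * np.einsum("ga,gb->ab", self.N, self.N)
        Ke = self.w * np.einsum("gad,gbd->ab", self.dN, self.dN)
        rows = np.repeat(self.conn, 8, axis=1).ravel()
        cols = np.tile(self.conn, (1, 8)).ravel()
        ne = len(self.conn)
        self.M = sp.coo_matrix(
            (np.tile(Me.ravel(), ne), (rows, cols)), shape=(n, n)
        ).tocsr()
        if lumped_mass:
            self.M = sp.diags(np.asarray(self.M.sum(axis=1)).ravel()).tocsr()
        self.K = sp.coo_matrix(
            (np.tile(Ke.ravel(), ne), (rows, cols)), shape=(n, n)
        ).tocsr()
        self._rows, self._cols = rows, cols
        self.node_weights = np.asarray(self.M.sum(axis=1)).ravel()
        # nodes of inactive elements only: pinned to keep systems regular
        orphan = np.setdiff1d(np.arange(n), np.unique(self.conn))
        ind = np.zeros(n)
        ind[orphan] = 1.0
        self.orphan_nodes = orphan
        self.orphan_identity = sp.diags(ind).tocsr()
        self.base_cache: dict = {}

    # -- gradients and interpolation at Gauss points --------------------

    def at_gauss(self, nodal: np.ndarray) -> np.ndarray:
        """Interpolate a nodal field to (n_active_elements, 8gp)."""
        return np.einsum("ga,ea->eg", self.N, nodal[self.conn])

    def grad_at_gauss(self, nodal: np.ndarray) -> np.ndarray:
        """Gradient of a nodal field at Gauss points, (E, 8gp, 3)."""
        return np.einsum("gad,ea->egd", self.dN, nodal[self.conn])

    def gp_to_nodes(self, gp_values: np.ndarray) -> np.ndarray:
        """Volume-weighted transfer of Gauss-point data to nodes."""
        num = np.zeros(self.mesh.n_nodes)
        den = np.zeros(self.mesh.n_nodes)
        contrib = self.w * np.einsum("ga,eg->ea", self.N, gp_values)
        weight = self.w * self.N.sum(axis=0)  # per local node
        np.add.at(num, self.conn.ravel(), contrib.ravel())
        np.add.at(den, self.conn.ravel(), np.tile(weight, (len(self.conn), 1)).ravel())
        out = np.zeros_like(num)
        good = den > 0
        out[good] = num[good] / den[good]
        return out

    def load_vector(self, gp_values: np.ndarray) -> np.ndarray:
        """Assemble ∫ N_i f dV from Gauss-point values of f."""
        out = np.zeros(self.mesh.n_nodes)
        contrib = self.w * np.einsum("ga,eg->ea", self.N, gp_values)
        np.add.at(out, self.conn.ravel(), contrib.ravel())
        return out

    def advection_matrix(self, c: np.ndarray, params: MaterialParams) -> sp.csr_matrix:
        """A_ij = ∫ N_i monod(c) (n_gradc . grad N_j) dV over active elements."""
        c_gp = self.at_gauss(c)
        g_gp = self.grad_at_gauss(c)
        norm = np.linalg.norm(g_gp, axis=-1)
        good = norm >= params.eps_grad
        coeff = np.where(good, monod_rate(np.maximum(c_gp, 0.0), params.r, params.k), 0.0)
        direction = np.where(
            good[..., None], g_gp / np.where(good, norm, 1.0)[..., None], 0.0
        )
        # (E, 8gp, 8b): n . grad N_b ; then weight by N_a and integrate
        ngrad = np.einsum("egd,gbd->egb", direction, self.dN)
        Ae = self.w * np.einsum("eg,ga,egb->eab", coeff, self.N, ngrad)
        n = self.mesh.n_nodes
        return sp.coo_matrix((Ae.ravel(), (self._rows, self._cols)), shape=(n, n)).tocsr()

    def mean(self, nodal: np.ndarray) -> float:
        """Volume-weighted domain average over active elements."""
        wsum = self.node_weights.sum()
        return float(self.node_weights @ nodal / wsum)


def get_operators(mesh: Mesh, lumped_mass: bool = False) -> FieldOperators:
    """Fetch (and cache on the mesh) the assembled operators."""
    cache = getattr(mesh, "_field_ops", None)
    if cache is None or cache.mesh is not mesh or (lumped_mass and not getattr(cache, "_lumped", False)):
        cache = FieldOperators(mesh, lumped_mass=lumped_mass)
        cache._lumped = lumped_mass
        mesh._field_ops = cache  # type: ignore[attr-defined]
    return cache


def _apply_dirichlet(S: sp.csr_matrix, rhs: np.ndarray, idx: np.ndarray, value: float):
    if len(idx) == 0:
        return S, rhs
    S = S.tolil()
    S[idx, :] = 0.0
    S[idx, idx] = 1.0
    rhs = rhs.copy()
    rhs[idx] = value
    return S.tocsr(), rhs


class LinearSolver:
    """Sparse direct solve (fresh LU factorization per call)."""

    def solve(
        self,
        S: sp.csr_matrix,
        rhs: np.ndarray,
        key: str = "",
        base: Optional[sp.csr_matrix] = None,
        symmetric: bool = False,
    ) -> np.ndarray:
        try:
            return spla.splu(S.tocsc()).solve(rhs)
        except RuntimeError as exc:
            raise SolverFailure(f"{key} system solve failed: {exc}") from exc


class CachedKrylovSolver(LinearSolver):
    """Iterative solves preconditioned by a once-factorized base matrix.

    Both field systems are a *constant* matrix (mass/dt + diffusion,
    factorized once per step size and cached under ``key``) plus a
    drifting but subordinate part (the Monod advection of the phase
    field; the consumption diagonal of the nutrients).  Symmetric
    systems are solved with base-preconditioned conjugate gradients,
    nonsymmetric ones with base-LU iterative refinement; both check the
    true residual against ``rtol`` and fall back to a direct
    factorization of the full matrix if they stall.  Entirely
    deterministic.
    """

    def __init__(self, rtol: float = 1e-11, max_iter: int = 80):
        self.rtol = rtol
        self.max_iter = max_iter
        self._base_lu: dict = {}

    def solve(
        self,
        S: sp.csr_matrix,
        rhs: np.ndarray,
        key: str = "",
        base: Optional[sp.csr_matrix] = None,
        symmetric: bool = False,
    ) -> np.ndarray:
        bnorm = np.linalg.norm(rhs)
        if bnorm == 0.0:
            return np.zeros_like(rhs)
        if base is None:
            return super().solve(S, rhs, key)
        lu = self._base_lu.get(key)
        if lu is None:
            try:
                lu = spla.splu(base.tocsc())
            except RuntimeError as exc:
                raise SolverFailure(f"{key} base factorization failed: {exc}") from exc
            self._base_lu[key] = lu
        tol = self.rtol * bnorm
        if symmetric:
            M = spla.LinearOperator(S.shape, matvec=lu.solve)
            x, info = spla.cg(
                S, rhs, x0=lu.solve(rhs), M=M, rtol=self.rtol, atol=0.0,
                maxiter=self.max_iter,
            )
            if info == 0 and np.linalg.norm(rhs - S @ x) <= 10 * tol:
                return x
        else:
            x = lu.solve(rhs)
            last = np.inf
            for _ in range(self.max_iter):
                r = rhs - S @ x
                rel = np.linalg.norm(r)
                if rel <= tol:
                    return x
                if rel >= 0.9 * last:
                    break
                last = rel
                x = x + lu.solve(r)
        logger.debug("%s: base-preconditioned solve stalled; direct fallback", key)
        return super().solve(S, rhs, key)


def assemble_c_system(
    state: FieldState,
    mesh: Mesh,
    bvp: Optional[BVPSpec],
    dt: float,
    params: MaterialParams,
    ops: Optional[FieldOperators] = None,
    c_lin: Optional[np.ndarray] = None,
) -> Tuple[sp.csr_matrix, np.ndarray]:
    """System matrix and right-hand side of one nutrient substep.

    Backward Euler on ``dc/dt = d lap(c) - g phi s(c)`` with the
    shutoff factor ``s(c) = c/(c + c_shutoff)`` linearized about
    ``c_lin`` (Picard: the sink becomes the implicit diagonal term
    ``g phi / (c_lin + c_shutoff) * c``).  With ``c_shutoff = 0`` the
    sink is the bare explicit ``g phi_n`` load.  Dirichlet rows for the
    source set are replaced by identity.
    """
    ops = ops or get_operators(mesh)
    S = (ops.M / dt + params.d * ops.K + ops.orphan_identity).tocsr()
    rhs = ops.M @ (state.c / dt)
    if params.g:
        if params.c_shutoff > 0:
            ref = state.c if c_lin is None else c_lin
            coeff = params.g * state.phi / (np.maximum(ref, 0.0) + params.c_shutoff)
            S = S + sp.diags(ops.node_weights * coeff)
        else:
            rhs = rhs - params.g * (ops.M @ state.phi)
    if bvp is not None:
        idx = np.asarray(mesh.node_sets[bvp.c_dirichlet[0]])
        S, rhs = _apply_dirichlet(S, rhs, idx, bvp.c_dirichlet[1])
    return S, rhs


def step_c(
    state: FieldState,
    mesh: Mesh,
    bvp: Optional[BVPSpec],
    dt: float,
    params: MaterialParams,
    ops: Optional[FieldOperators] = None,
    solver: Optional[LinearSolver] = None,
    picard_iterations: int = 1,
) -> np.ndarray:
    """One backward-Euler step of the nutrient equation.

    Solves ``(M/dt + d K) c1 = M c0/dt - sink`` with c = 1 held on the
    source set (if a BVP is given) and zero-flux elsewhere.  The
    exhaustion-regularized sink (see :class:`MaterialParams.c_shutoff`)
    is implicit with its shutoff factor linearized about the previous
    substep's concentration (one extra Picard sweep per unit of
    ``picard_iterations`` re-linearizes within the substep); the result
    is clamped onto [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops or get_operators(mesh)
    solver = solver or LinearSolver()
    n = mesh.n_nodes
    if bvp is not None:
        dir_idx = np.asarray(mesh.node_sets[bvp.c_dirichlet[0]], dtype=np.int64)
        value = bvp.c_dirichlet[1]
    else:
        dir_idx, value = np.empty(0, dtype=np.int64), 0.0
    dir_all = np.union1d(dir_idx, ops.orphan_nodes)
    dir_vals = np.where(np.isin(dir_all, dir_idx), value, 0.0)
    key = f"c/{dt:.6e}/{params.d:.6e}/{len(dir_all)}"
    cached = ops.base_cache.get(key)
    if cached is None:
        S0 = (ops.M / dt + params.d * ops.K).tocsr()
        free = np.setdiff1d(np.arange(n), dir_all)
        cached = {
            "free": free,
            "S0_ff": S0[free][:, free].tocsr(),
            "S0_fd": S0[free][:, dir_all].tocsr(),
        }
        ops.base_cache[key] = cached
    free = cached["free"]
    c_new = state.c
    for it in range(picard_iterations):
        S_ff = cached["S0_ff"]
        if params.g and params.c_shutoff > 0:
            coeff = params.g * state.phi / (np.maximum(c_new, 0.0) + params.c_shutoff)
            S_ff = S_ff + sp.diags((ops.node_weights * coeff)[free])
        rhs = ops.M @ (state.c / dt)
        if params.g and params.c_shutoff == 0:
            rhs = rhs - params.g * (ops.M @ state.phi)
        rhs_f = rhs[free] - cached["S0_fd"] @ dir_vals
        c_prev = c_new
        sol = solver.solve(S_ff, rhs_f, key, base=cached["S0_ff"], symmetric=True)
        c_new = np.zeros(n)
        c_new[dir_all] = dir_vals
        c_new[free] = sol
        if not np.all(np.isfinite(c_new)):
            raise SolverFailure("nutrient solve returned non-finite values")
        if it > 0 and np.abs(c_new - c_prev).max() < 1e-9:
            break
    over = np.count_nonzero((c_new < -1e-9) | (c_new > 1 + 1e-9))
    if over:
        logger.debug("step_c: clamping %d nodes outside [0,1]", over)
    return project_bounds(c_new, 0.0, 1.0)


def assemble_phi_system(
    state: FieldState,
    mesh: Mesh,
    bvp: Optional[BVPSpec],
    dt: float,
    params: MaterialParams,
    c_used: np.ndarray,
    ops: Optional[FieldOperators] = None,
    mech_coupling: bool = False,
) -> Tuple[sp.csr_matrix, np.ndarray]:
    """System matrix and right-hand side of one phase-field substep."""
    ops = ops or get_operators(mesh)
    A = ops.advection_matrix(c_used, params)
    S = (ops.M / dt + params.beta * ops.K + ops.orphan_identity + A).tocsr()
    alpha_nodes = ops.gp_to_nodes(state.alpha[mesh.active_mask])
    rhs = ops.M @ (state.phi / dt + params.k_alpha * alpha_nodes)
    if mech_coupling:
        from .kinematics import elastic_decomposition  # local import, no cycle
        F = _deformation_gradients(ops, state.u)
        alpha_gp = state.alpha[mesh.active_mask]
        _, Ce, _ = elastic_decomposition(F, alpha_gp)
        trCe = np.einsum("egii->eg", Ce)
        phi_gp = ops.at_gauss(state.phi)
        rhs -= ops.load_vector(params.mu * phi_gp * (trCe - 3.0))
    if bvp is not None and bvp.phi_held_fixed:
        S, rhs = _apply_dirichlet(S, rhs, mesh.node_sets[bvp.phi_init_set], 1.0)
    return S, rhs


def step_phi(
    state: FieldState,
    mesh: Mesh,
    bvp: Optional[BVPSpec],
    dt: float,
    params: MaterialParams,
    c_new: Optional[np.ndarray] = None,
    ops: Optional[FieldOperators] = None,
    solver: Optional[LinearSolver] = None,
    lag_gradient: bool = False,
    mech_coupling: bool = False,
) -> np.ndarray:
    """One backward-Euler step of the biofilm phase field.

    The equation is linear in phi_{n+1}: diffusion and the directional
    Monod advection act implicitly, the local-expansion source
    ``k_alpha * alpha`` (transferred from Gauss points to nodes) acts
    explicitly.  With ``lag_gradient`` the nutrient direction of the
    previous step is used instead of the freshly advanced one.  The
    optional ``mech_coupling`` flag restores the (by default neglected)
    elastic feedback term ``phi mu (I:Ce - 3)`` explicitly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops or get_operators(mesh)
    solver = solver or LinearSolver()
    c_used = state.c if (c_new is None or lag_gradient) else c_new
    S, rhs = assemble_phi_system(state, mesh, bvp, dt, params, c_used, ops, mech_coupling)
    held = bvp is not None and bvp.phi_held_fixed
    key = f"phi/{dt:.6e}/{params.beta:.6e}/{int(held)}"
    base = ops.base_cache.get(key)
    if base is None:
        base = (ops.M / dt + params.beta * ops.K + ops.orphan_identity).tocsr()
        if held:
            base, _ = _apply_dirichlet(base, np.zeros(mesh.n_nodes),
                                       mesh.node_sets[bvp.phi_init_set], 1.0)
        ops.base_cache[key] = base
    phi_new = solver.solve(S, rhs, key, base=base, symmetric=False)
    if not np.all(np.isfinite(phi_new)):
        raise SolverFailure("phase-field solve returned non-finite values")
    over = np.count_nonzero((phi_new < -1e-9) | (phi_new > 1 + 1e-9))
    if over:
        logger.debug("step_phi: clamping %d nodes outside [0,1]", over)
    return project_bounds(phi_new, 0.0, 1.0)


def _deformation_gradients(ops: FieldOperators, u: np.ndarray) -> np.ndarray:
    """F = I + du/dX at the Gauss points of active elements, (E, 8, 3, 3)."""
    grads = np.einsum("gad,eai->egid", ops.dN, u[ops.conn])
    return np.eye(3)[None, None] + grads
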