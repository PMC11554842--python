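"""Quasi-static incompressible neo-Hookean mechanics with growth.

The element is the classical Q1P0 (H1P0) brick: trilinear displacements
with one constant hydrostatic-stress unknown p per element acting as the
Lagrange multiplier of det(Fe) = 1.  Growth enters through the
multiplicative split Fe = F / (1 + alpha) with the Gauss-point expansion
alpha supplied by the growth fields; the coupling is one-way, so the
mechanical solve is a post-state of each growth substep.

The strain energy is phi^2 (mu/2) (I : C~e - 3) on the isochoric
invariant C~e = Je^(-2/3) Ce (identical to the raw Ce once the
constraint holds, but with the practical property that the stress-free
grown state carries p = 0).  Void regions (phi ~ 0) keep an ersatz
stiffness floor so the global system stays definite.

With the exact multiplier the pressure diagonal of the element tangent
is structurally zero, so the default solver assembles the global
saddle-point system in (u, p) and factorizes it directly.  Passing a
finite compressibility penalty ``kappa`` switches to the perturbed
Lagrangian (energy term -p^2/(2 kappa)), which makes K_pp invertible and
enables classical per-element static condensation of p via the Schur
complement; both routes then solve the same perturbed problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import FieldOperators, FieldState, MaterialParams, SolverFailure, get_operators
from .meshing import Mesh, BVPSpec

logger = logging.getLogger("biofilmsim")

__all__ = [
    "ElementSystem",
    "strain_energy_density",
    "cauchy_stress",
    "element_system",
    "condense_pressure",
    "solve_mechanics",
    "sliding_constraints",
    "NonConvergence",
]


class NonConvergence(SolverFailure):
    """The Newton iteration did not converge (or the system is infeasible)."""


@dataclass
class ElementSystem:
    """Mechanical element block: 24 displacement DOFs + 1 pressure."""

    residual: np.ndarray          # (25,)
    stiffness: np.ndarray         # (25, 25)
    internal_sensitivity: np.ndarray = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.internal_sensitivity is None:
            self.internal_sensitivity = np.zeros(25)


# ---------------------------------------------------------------------------
# pointwise constitutive functions
# ---------------------------------------------------------------------------

def strain_energy_density(Ce, phi, mu: float, isochoric: bool = False):
    """Neo-Hookean energy density phi^2 (mu/2)(I : Ce - 3) in Pa.

    Vanishes in the undeformed state and in the void (phi = 0).  With
    ``isochoric=True`` the invariant is evaluated on
    Je^(-2/3) Ce, the form actually used in assembly (the two coincide
    when det Fe = 1).
    """
    Ce = np.asarray(Ce, dtype=float)
    tr = np.einsum("...ii->...", Ce)
    if isochoric:
        tr = np.linalg.det(Ce) ** (-1.0 / 3.0) * tr
    return np.asarray(phi) ** 2 * 0.5 * mu * (tr - 3.0)


def cauchy_stress(Fe, phi, p, mu: float):
    """Cauchy stress of the incompressible neo-Hookean law.

    sigma = phi^2 mu Je^(-5/3) dev(Be) + p I   (Be = Fe Fe^T),
    tension-positive; purely hydrostatic (= p I) at Fe = I.
    """
    Fe = np.asarray(Fe, dtype=float)
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise ValueError("det Fe must be positive")
    Be = Fe @ np.swapaxes(Fe, -1, -2)
    trB = np.einsum("...ii->...", Be)
    dev = Be - (trB / 3.0)[..., None, None] * np.eye(3)
    coeff = np.asarray(phi) ** 2 * mu * Je ** (-5.0 / 3.0)
    return coeff[..., None, None] * dev + np.asarray(p)[..., None, None] * np.eye(3)


# ---------------------------------------------------------------------------
# element assembly (vectorized over elements)
# ---------------------------------------------------------------------------

def _assemble_elements(
    ops: FieldOperators,
    u: np.ndarray,
    p: np.ndarray,
    phi: np.ndarray,
    alpha_gp: np.ndarray,
    params: MaterialParams,
    kappa: Optional[float],
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Residual (E,25) and tangent (E,25,25) for all active elements.

    ``p`` and ``alpha_gp`` are per active element; returns the maximum
    |Je - 1| over all Gauss points as a constraint diagnostic.
    """
    conn = ops.conn
    E = len(conn)
    w = ops.w
    Ve = w * 8.0
    eye = np.eye(3)

    phi_gp_all = ops.at_gauss(phi)                       # (E, 8)
    u_el = u[conn]                                       # (E, 8, 3)

    R = np.zeros((E, 25))
    K = np.zeros((E, 25, 25))
    max_dev = 0.0

    for g in range(8):
        dN = ops.dN[g]                                   # (8, 3)
        F = eye[None] + np.einsum("ad,eai->eid", dN, u_el)
        detF = np.linalg.det(F)
        if np.any(detF <= 0):
            raise SolverFailure("inverted element (det F <= 0)")
        stretch = 1.0 + alpha_gp[:, g]
        Fe = F / stretch[:, None, None]
        Je = detF / stretch**3
        H = np.linalg.inv(np.swapaxes(Fe, -1, -2))       # Fe^{-T}
        t = np.einsum("eij,eij->e", Fe, Fe)              # tr Ce
        a = (phi_gp_all[:, g] ** 2 + params.stiffness_floor) * params.mu
        c23 = Je ** (-2.0 / 3.0)
        max_dev = max(max_dev, float(np.abs(Je - 1.0).max()))

        # first Piola-Kirchhoff stress w.r.t. Fe, then chain by 1/(1+alpha)
        dPsi_dFe = (
            (a * c23)[:, None, None] * (Fe - (t / 3.0)[:, None, None] * H)
            + (p * Je)[:, None, None] * H
        )
        P = dPsi_dFe / stretch[:, None, None]
        Ru = w * np.einsum("eiJ, aJ -> eai", P, dN)      # (E, 8, 3)
        R[:, :24] += Ru.reshape(E, 24)
        R[:, 24] += w * (Je - 1.0)

        # material tangent d2Psi/dFe2 (E,3,3,3,3)
        ac = a * c23
        D = np.einsum("e,ik,JL->eiJkL", ac, eye, eye)
        D -= (2.0 / 3.0) * np.einsum("e,eiJ,ekL->eiJkL", ac, Fe, H)
        D -= (2.0 / 3.0) * np.einsum("e,ekL,eiJ->eiJkL", ac, Fe, H)
        D += (2.0 / 9.0) * np.einsum("e,eiJ,ekL->eiJkL", ac * t, H, H)
        D += (1.0 / 3.0) * np.einsum("e,ekJ,eiL->eiJkL", ac * t, H, H)
        pJ = p * Je
        D += np.einsum("e,eiJ,ekL->eiJkL", pJ, H, H)
        D -= np.einsum("e,ekJ,eiL->eiJkL", pJ, H, H)

        Kuu = (w / stretch**2)[:, None, None, None, None] * np.einsum(
            "eiJkL,aJ,bL->eaibk", D, dN, dN, optimize=True
        )
        K[:, :24, :24] += Kuu.reshape(E, 24, 24)

        Kup = (w * Je / stretch)[:, None, None] * np.einsum("eiJ,aJ->eai", H, dN)
        K[:, :24, 24] += Kup.reshape(E, 24)
        K[:, 24, :24] += Kup.reshape(E, 24)

    if kappa is not None:
        R[:, 24] -= Ve * p / kappa
        K[:, 24, 24] -= Ve / kappa
    return R, K, max_dev


def element_system(
    mesh: Mesh,
    element: int,
    state: FieldState,
    params: MaterialParams,
    kappa: Optional[float] = None,
) -> ElementSystem:
    """Residual and consistent tangent of one active element.

    In the staggered design alpha is frozen during the mechanical solve,
    so the internal sensitivity d(alpha)/d(DOFs) is identically zero.
    """
    ops = get_operators(mesh)
    active = mesh.active_elements
    pos = np.nonzero(active == element)[0]
    if len(pos) == 0:
        raise ValueError(f"element {element} is not active")
    e = int(pos[0])
    sub = _SingleElementOps(ops, e)
    R, K, _ = _assemble_elements(
        sub, state.u, state.p[element : element + 1], state.phi,
        state.alpha[element : element + 1], params, kappa,
    )
    return ElementSystem(R[0], K[0])


class _SingleElementOps:
    """View of the cached operators restricted to one active element."""

    def __init__(self, ops: FieldOperators, local_index: int):
        self.conn = ops.conn[local_index : local_index + 1]
        self.dN = ops.dN
        self.N = ops.N
        self.w = ops.w

    def at_gauss(self, nodal):
        return np.einsum("ga,ea->eg", self.N, nodal[self.conn])


def condense_pressure(system: ElementSystem, tol: float = 1e-14):
    """Eliminate the element pressure by the Schur complement.

    Returns ``(K_cond, R_cond, recover)`` with
    K_cond = K_DD - K_Dp K_pp^-1 K_pD and ``recover(du) -> dp`` for
    post-processing the pressure update.  Requires an invertible K_pp
    (perturbed Lagrangian); a |K_pp| below ``tol`` is reported as a
    near-incompressibility degeneracy.
    """
    K = np.asarray(system.stiffness, dtype=float)
    R = np.asarray(system.residual, dtype=float)
    kpp = K[-1, -1]
    if abs(kpp) < tol:
        raise SolverFailure(
            "pressure diagonal is (near) zero; static condensation needs the "
            "perturbed-Lagrangian formulation (finite kappa)"
        )
    kdp = K[:-1, -1]
    kpd = K[-1, :-1]
    K_cond = K[:-1, :-1] - np.outer(kdp, kpd) / kpp
    R_cond = R[:-1] - kdp * (R[-1] / kpp)

    def recover(du: np.ndarray) -> float:
        return float(-(R[-1] + kpd @ du) / kpp)

    return K_cond, R_cond, recover


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def sliding_constraints(mesh: Mesh) -> List[Tuple[np.ndarray, int]]:
    """Frictionless wall constraints from the active-element mask.

    For every grid face separating an active element from an inactive
    (rigid) one, the shared nodes lose the displacement component normal
    to that face: the biofilm domain may slide along obstacle surfaces
    but not penetrate them.  Returns ``(node_indices, axis)`` pairs.
    """
    nx, ny, nz = mesh.shape
    act = mesh.active_mask.reshape(nz, ny, nx).transpose(2, 1, 0)  # [i,j,k]
    conn = mesh.element_conn.reshape(nz, ny, nx, 8).transpose(2, 1, 0, 3)
    # local node ids of the faces with outward normal along -x,+x,-y,+y,-z,+z
    faces = {
        (0, -1): [0, 3, 7, 4], (0, 1): [1, 2, 6, 5],
        (1, -1): [0, 1, 5, 4], (1, 1): [3, 2, 6, 7],
        (2, -1): [0, 1, 2, 3], (2, 1): [4, 5, 6, 7],
    }
    found: dict = {0: set(), 1: set(), 2: set()}
    for (axis, sign), local in faces.items():
        shift = np.zeros(3, dtype=int)
        shift[axis] = sign
        pad = np.zeros(np.array(act.shape) + 2, dtype=bool)
        pad[1:-1, 1:-1, 1:-1] = act
        neigh = pad[
            1 + shift[0] : act.shape[0] + 1 + shift[0],
            1 + shift[1] : act.shape[1] + 1 + shift[1],
            1 + shift[2] : act.shape[2] + 1 + shift[2],
        ]
        sel = act & ~neigh
        # interior faces only: a missing neighbour beyond the boundary is
        # the free surface, not a wall
        idx = np.argwhere(sel)
        for i, j, k in idx:
            pos = np.array([i, j, k]) + shift
            if np.any(pos < 0) or np.any(pos >= np.array(act.shape)):
                continue
            found[axis].update(conn[i, j, k, local].tolist())
    return [
        (np.array(sorted(nodes), dtype=np.int64), axis)
        for axis, nodes in found.items()
        if nodes
    ]


def _fixed_dofs(mesh: Mesh, bvp: Optional[BVPSpec]) -> np.ndarray:
    fixed = set()
    if bvp is not None:
        for set_name, comps in bvp.mech_constraints:
            for n in mesh.node_sets[set_name]:
                for comp in comps:
                    fixed.add(3 * int(n) + comp)
        if not np.all(mesh.active_mask):
            for nodes, axis in sliding_constraints(mesh):
                for n in nodes:
                    fixed.add(3 * int(n) + axis)
    # nodes not attached to any active element carry no stiffness: pin them
    orphan = np.setdiff1d(np.arange(mesh.n_nodes), mesh.active_nodes)
    for n in orphan:
        fixed.update((3 * int(n), 3 * int(n) + 1, 3 * int(n) + 2))
    return np.array(sorted(fixed), dtype=np.int64)


# ---------------------------------------------------------------------------
# global Newton solve
# ---------------------------------------------------------------------------

def solve_mechanics(
    mesh: Mesh,
    state: FieldState,
    bvp: Optional[BVPSpec],
    params: MaterialParams,
    tol: float = 1e-10,
    rtol: float = 1e-12,
    max_iter: int = 30,
    kappa: Optional[float] = None,
    method: str = "saddle",
    je_tol: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Global Newton iteration for (u, p) at the current growth state.

    ``method="saddle"`` (default) solves the assembled saddle-point
    system for displacements and element pressures together and works
    with the exact multiplier (``kappa=None``).  ``method="condensed"``
    eliminates p element-wise first and requires a finite ``kappa``.
    Returns ``(u, p, n_iterations)``; raises :class:`NonConvergence` on
    stagnation or infeasible constraints and :class:`SolverFailure` on
    element inversion, both of which signal substep bisection upstream.
    """
    if method == "condensed" and kappa is None:
        raise ValueError("the condensed path requires a finite kappa")
    ops = get_operators(mesh)
    active = mesh.active_elements
    E = len(active)
    n_u = 3 * mesh.n_nodes
    conn = ops.conn
    udofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(E, 24)

    fixed = _fixed_dofs(mesh, bvp)
    free_u = np.setdiff1d(np.arange(n_u), fixed)

    u = state.u.copy()
    u.reshape(-1)[fixed] = 0.0
    p = state.p[active].copy()
    alpha_gp = state.alpha[active]

    r0 = None
    for it in range(max_iter + 1):
        R_el, K_el, max_dev = _assemble_elements(
            ops, u, p, state.phi, alpha_gp, params, kappa
        )
        Ru = np.zeros(n_u)
        np.add.at(Ru, udofs.ravel(), R_el[:, :24].ravel())
        Rp = R_el[:, 24]
        res = np.linalg.norm(np.concatenate([Ru[free_u], Rp]))
        if r0 is None:
            r0 = res
        logger.debug("mechanics Newton it=%d |R|=%.3e |Je-1|max=%.3e", it, res, max_dev)
        if res <= max(tol, rtol * r0):
            # the constant-pressure multiplier controls the element MEAN
            # of Je - 1 (pointwise values vary within the element by the
            # local strain gradient); the perturbed Lagrangian only
            # enforces it up to |p|/kappa, so the check applies to the
            # exact formulation
            mean_dev = np.abs(Rp).max() / (8.0 * ops.w)
            if kappa is None and mean_dev > je_tol:
                raise NonConvergence(
                    f"converged residual but element-mean |Je-1|="
                    f"{mean_dev:.2e} exceeds {je_tol:.0e}"
                )
            out_p = np.zeros(mesh.n_elements)
            out_p[active] = p
            return u, out_p, it
        if it == max_iter:
            raise NonConvergence(
                f"mechanics Newton stagnated at |R|={res:.3e} after {max_iter} iterations"
            )

        if method == "saddle":
            du_full, dp = _saddle_step(
                K_el, Ru, Rp, udofs, free_u, n_u, E
            )
        else:
            du_full, dp = _condensed_step(K_el, R_el, Ru, udofs, free_u, n_u, E)
        u = u + du_full.reshape(-1, 3)
        p = p + dp
    raise NonConvergence("unreachable")


def _saddle_step(K_el, Ru, Rp, udofs, free_u, n_u, E):
    rows_uu = np.repeat(udofs, 24, axis=1).ravel()
    cols_uu = np.tile(udofs, (1, 24)).ravel()
    vals_uu = K_el[:, :24, :24].ravel()
    pdofs = n_u + np.arange(E)
    rows_up = np.repeat(udofs, 1, axis=1).ravel()
    cols_up = np.repeat(pdofs[:, None], 24, axis=1).ravel()
    vals_up = K_el[:, :24, 24].ravel()
    vals_pu = K_el[:, 24, :24].ravel()
    vals_pp = K_el[:, 24, 24]
    ndof = n_u + E
    A = sp.coo_matrix(
        (
            np.concatenate([vals_uu, vals_up, vals_pu, vals_pp]),
            (
                np.concatenate([rows_uu, rows_up, cols_up, pdofs]),
                np.concatenate([cols_uu, cols_up, rows_up, pdofs]),
            ),
        ),
        shape=(ndof, ndof),
    ).tocsr()
    keep = np.concatenate([free_u, pdofs])
    A = A[keep][:, keep].tocsc()
    rhs = -np.concatenate([Ru[free_u], Rp])
    try:
        sol = spla.splu(A).solve(rhs)
    except RuntimeError as exc:
        raise NonConvergence(f"singular mechanics system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise NonConvergence("mechanics solve returned non-finite values")
    du_full = np.zeros(n_u)
    du_full[free_u] = sol[: len(free_u)]
    return du_full, sol[len(free_u):]


def _condensed_step(K_el, R_el, Ru, udofs, free_u, n_u, E):
    kpp = K_el[:, 24, 24]
    if np.any(np.abs(kpp) < 1e-14):
        raise SolverFailure("zero pressure diagonal in condensed path")
    kdp = K_el[:, :24, 24]
    kpd = K_el[:, 24, :24]
    Kc = K_el[:, :24, :24] - np.einsum("ea,eb->eab", kdp, kpd) / kpp[:, None, None]
    Rc_el = R_el[:, :24] - kdp * (R_el[:, 24] / kpp)[:, None]
    Rc = np.zeros(n_u)
    np.add.at(Rc, udofs.ravel(), Rc_el.ravel())
    rows = np.repeat(udofs, 24, axis=1).ravel()
    cols = np.tile(udofs, (1, 24)).ravel()
    A = sp.coo_matrix((Kc.ravel(), (rows, cols)), shape=(n_u, n_u)).tocsr()
    A = A[free_u][:, free_u].tocsc()
    try:
        sol = spla.splu(A).solve(-Rc[free_u])
    except RuntimeError as exc:
        raise NonConvergence(f"singular condensed system: {exc}") from exc
    du_full = np.zeros(n_u)
    du_full[free_u] = sol
    du_el = du_full[udofs]
    dp = -(R_el[:, 24] + np.einsum("ea,ea->e", kpd, du_el)) / kpp
    return du_full, dp
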