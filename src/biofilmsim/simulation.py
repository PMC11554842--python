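"""Time stepping over normalized time with substep bisection.

A run advances the state over T* in [0, 1] with a staggered update per
substep: nutrients first (they are the fast, quasi-steady field), then
the biofilm phase field with the fresh nutrient gradient, then the
Gauss-point expansion variable, and - at a configurable cadence - the
quasi-static mechanical solve.  Any solver failure halves the substep
and retries, up to the equivalent of ``n_substeps_max`` steps; the
model itself is deterministic, so identical inputs reproduce identical
trajectories bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from . import fields as flds
from . import kinematics as kin
from . import mechanics as mech
from .fields import FieldState, MaterialParams, SolverFailure
from .meshing import Mesh, BVPSpec

logger = logging.getLogger("biofilmsim")

__all__ = ["Schedule", "Trajectory", "run_simulation", "summarize_state", "detect_fill_time"]

FILL_THRESHOLD = 0.8  # phi level of the rendered biofilm isosurface


@dataclass
class Schedule:
    """Time-stepping schedule over normalized time.

    ``n_substeps_nominal`` sets the nominal substep ``t_end / n``;
    bisection may refine it down to the equivalent of
    ``n_substeps_max`` substeps.  ``mechanics_cadence`` is the number of
    nominal substeps between mechanical solves (0 disables mechanics;
    1 recovers a per-substep solve).  ``seed`` is recorded for
    provenance only - the model has no randomness.
    """

    t_end: float = 1.0
    n_substeps_nominal: int = 1000
    n_substeps_max: int = 10**6
    bisection_factor: int = 2
    output_every: int = 10
    mechanics_cadence: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_substeps_nominal <= 0 or self.n_substeps_max <= 0:
            raise ValueError("substep counts must be positive")
        if self.n_substeps_nominal > self.n_substeps_max:
            raise ValueError("n_substeps_nominal must not exceed n_substeps_max")
        if self.bisection_factor < 2:
            raise ValueError("bisection_factor must be at least 2")


@dataclass
class Trajectory:
    """Recorded summary statistics of one run."""

    times: List[float] = field(default_factory=list)
    mean_phi: List[float] = field(default_factory=list)
    mean_c: List[float] = field(default_factory=list)
    fill_fraction: List[float] = field(default_factory=list)
    snapshot_refs: List[str] = field(default_factory=list)
    n_substeps_taken: int = 0
    n_bisections: int = 0
    newton_iterations: List[int] = field(default_factory=list)

    def record(self, t: float, stats: Tuple[float, float, float]) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("record times must be strictly increasing")
        self.times.append(t)
        self.mean_phi.append(stats[0])
        self.mean_c.append(stats[1])
        self.fill_fraction.append(stats[2])

    def as_columns(self) -> dict:
        return {
            "t_star": self.times,
            "mean_phi": self.mean_phi,
            "mean_c": self.mean_c,
            "fill_fraction": self.fill_fraction,
        }


def summarize_state(state: FieldState, mesh: Mesh) -> Tuple[float, float, float]:
    """Volume-weighted domain averages and the filled-node fraction.

    Means are over active elements (consistent-mass weighting); the fill
    fraction counts nodes of active elements with phi >= 0.8, the
    isosurface level used to visualize the biofilm.
    """
    ops = flds.get_operators(mesh)
    nodes = mesh.active_nodes
    filled = float(np.count_nonzero(state.phi[nodes] >= FILL_THRESHOLD)) / len(nodes)
    return ops.mean(state.phi), ops.mean(state.c), filled


def detect_fill_time(trajectory: Trajectory, threshold: float = FILL_THRESHOLD) -> Optional[float]:
    """Earliest recorded time at which every node is filled, else None."""
    del threshold  # the records were taken at the standard isosurface level
    for t, f in zip(trajectory.times, trajectory.fill_fraction):
        if f >= 1.0 - 1e-12:
            return t
    return None


def run_simulation(
    mesh: Mesh,
    bvp: BVPSpec,
    params: MaterialParams,
    schedule: Schedule,
    snapshot_writer: Optional[Callable[[Mesh, FieldState, int], str]] = None,
    stop_when_filled: bool = False,
    alpha_variant: str = "rate_phi",
    lag_gradient: bool = False,
    lumped_mass: bool = False,
    mech_kwargs: Optional[dict] = None,
) -> Tuple[Trajectory, FieldState]:
    """Run one boundary value problem to ``schedule.t_end``.

    Returns the trajectory of summary statistics and the final state.
    On persistent solver failure the run aborts with the last good state
    preserved in the raised :class:`RuntimeError`'s ``state`` attribute.
    """
    ops = flds.get_operators(mesh, lumped_mass=lumped_mass)
    solver = flds.CachedKrylovSolver()
    state = flds.init_state(mesh, bvp)
    traj = Trajectory()
    traj.record(0.0, summarize_state(state, mesh))
    if snapshot_writer is not None:
        traj.snapshot_refs.append(snapshot_writer(mesh, state, 0))

    dt_nom = schedule.t_end / schedule.n_substeps_nominal
    dt_min = schedule.t_end / schedule.n_substeps_max
    record_dt = dt_nom * schedule.output_every
    next_record = record_dt
    mech_dt = dt_nom * schedule.mechanics_cadence if schedule.mechanics_cadence else None
    next_mech = mech_dt
    active = mesh.active_mask

    t = 0.0
    dt = dt_nom
    snap_index = 1
    while t < schedule.t_end - 1e-15:
        dt = min(dt, schedule.t_end - t)
        try:
            c_new = flds.step_c(state, mesh, bvp, dt, params, ops=ops, solver=solver)
            phi_new = flds.step_phi(
                state, mesh, bvp, dt, params, c_new=c_new, ops=ops, solver=solver,
                lag_gradient=lag_gradient,
            )
            phi_gp_old = ops.at_gauss(state.phi)
            phi_gp_new = ops.at_gauss(phi_new)
            alpha_new = state.alpha.copy()
            alpha_new[active] = kin.update_alpha(
                state.alpha[active], phi_gp_old, phi_gp_new, dt, params, alpha_variant
            )
            trial = FieldState(t + dt, phi_new, c_new, state.u, state.p, alpha_new)
            if next_mech is not None and trial.t_star >= next_mech - 1e-12:
                u, p, iters = mech.solve_mechanics(
                    mesh, trial, bvp, params, **(mech_kwargs or {})
                )
                trial.u, trial.p = u, p
                traj.newton_iterations.append(iters)
                next_mech += mech_dt
        except SolverFailure as exc:
            new_dt = dt / schedule.bisection_factor
            traj.n_bisections += 1
            logger.info("substep bisection at t=%.6f: %s (dt -> %.3e)", t, exc, new_dt)
            if new_dt < dt_min:
                err = RuntimeError(
                    f"substep fell below t_end/{schedule.n_substeps_max}; aborting"
                )
                err.state = state  # type: ignore[attr-defined]
                err.trajectory = traj  # type: ignore[attr-defined]
                raise err from exc
            dt = new_dt
            continue

        state = trial
        t = state.t_star
        traj.n_substeps_taken += 1
        if dt < dt_nom:
            dt = min(dt * schedule.bisection_factor, dt_nom)
        if t >= next_record - 1e-12 or t >= schedule.t_end - 1e-15:
            traj.record(t, summarize_state(state, mesh))
            while next_record <= t + 1e-12:
                next_record += record_dt
            if snapshot_writer is not None:
                traj.snapshot_refs.append(snapshot_writer(mesh, state, snap_index))
                snap_index += 1
            if stop_when_filled and traj.fill_fraction[-1] >= 1.0 - 1e-12:
                logger.info("domain filled at T*=%.4f; stopping early", t)
                break
    return traj, state
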