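"""Local expansion variable and the multiplicative growth split.

The deformation gradient splits as F = Fe . Fg with an isotropic,
stress-free growth map Fg = (1 + alpha) I driven by the local expansion
parameter alpha (a Gauss-point internal variable, alpha(t=0) = 0, growth
stretch 1 + alpha so the natural initial state is non-singular).  alpha
evolves with the biofilm density, d(alpha)/dt = k_alpha * phi, so it is
non-decreasing wherever biofilm is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import MaterialParams, SolverFailure

__all__ = [
    "GrowthTensors",
    "update_alpha",
    "growth_tensor",
    "elastic_decomposition",
]


@dataclass
class GrowthTensors:
    """Deformation split at one (or a batch of) material point(s)."""

    F: np.ndarray
    Fg: np.ndarray
    Fe: np.ndarray
    Ce: np.ndarray
    Je: np.ndarray


def update_alpha(
    alpha_n: np.ndarray,
    phi_n: np.ndarray,
    phi_np1: np.ndarray,
    dt: float,
    params: MaterialParams,
    variant: str = "rate_phi",
) -> np.ndarray:
    """Advance the expansion parameter by one substep.

    ``rate_phi`` (default) is backward Euler on the rate law
    ``d(alpha)/dt = k_alpha phi``:  alpha1 = alpha0 + dt k_alpha phi1.
    ``table1`` is the increment-driven local residual
    ``(a1 - a0)/((1 + a1) dt) = k_alpha (phi1 - phi0)/dt`` with the
    closed form a1 = (a0 + K)/(1 - K), K = k_alpha (phi1 - phi0); it is
    only solvable for K < 1 (a larger jump signals a too-large substep).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    alpha_n = np.asarray(alpha_n, dtype=float)
    phi_np1 = np.asarray(phi_np1, dtype=float)
    if variant == "rate_phi":
        return alpha_n + dt * params.k_alpha * phi_np1
    if variant == "table1":
        K = params.k_alpha * (phi_np1 - np.asarray(phi_n, dtype=float))
        if np.any(K >= 1.0):
            raise SolverFailure("alpha increment too large (K >= 1); bisect substep")
        return (alpha_n + K) / (1.0 - K)
    raise ValueError(f"unknown alpha update variant {variant!r}")


def growth_tensor(alpha):
    """Isotropic growth map Fg = (1 + alpha) I and its determinant.

    Batched: ``alpha`` of shape S returns Fg of shape S + (3, 3).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= -1.0):
        raise ValueError("alpha <= -1 would invert the growth map")
    stretch = 1.0 + alpha
    Fg = stretch[..., None, None] * np.eye(3)
    return Fg, stretch**3


def elastic_decomposition(F, alpha):
    """Split F into the elastic part given the growth state.

    Fe = F / (1 + alpha), Ce = Fe^T Fe, Je = det Fe.  Batched over any
    leading shape shared by F (..., 3, 3) and alpha (...).  Raises on
    inverted total deformation (det F <= 0).
    """
    F = np.asarray(F, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise SolverFailure("inverted element (det F <= 0); bisect substep")
    if np.any(alpha <= -1.0):
        raise ValueError("alpha <= -1 is non-physical")
    stretch = 1.0 + alpha
    Fe = F / stretch[..., None, None]
    Ce = np.swapaxes(Fe, -1, -2) @ Fe
    Je = detF / stretch**3
    return Fe, Ce, Je
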