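"""Linear stability of equilibria via the analytic Jacobian."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig

from .equilibria import Equilibrium
from .model_core import ModelParameters, State

__all__ = ["StabilityReport", "jacobian", "classify"]

#: real parts within this distance of zero are called marginal
STABILITY_TOL = 1e-8


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: np.ndarray  # 5 complex eigenvalues
    max_real_part: float
    label: str  # "stable" | "unstable" | "marginal"

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def jacobian(s: State | np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic 5x5 partial-derivative matrix of the vector field.

    Hand-derived; eigenvalues near thresholds need better accuracy than
    finite differences provide (the finite-difference check lives in the
    test suite).
    """
    y = s.as_array() if isinstance(s, State) else np.asarray(s, dtype=float)
    u, up, m, M, I = y
    if np.any(y < 0):
        raise ValueError("jacobian requires a non-negative state")

    J = np.zeros((5, 5))
    # d(du)/d(u, m)
    J[0, 0] = -p.gamma0 - p.tau0
    J[0, 2] = 2.0 * p.r1 * m
    # d(dup)/d(u, up)
    J[1, 0] = p.gamma0
    J[1, 1] = -p.taup
    # d(dm)/d(u, m, I); stress term tauS*I/(1+C*u^n)
    denom = 1.0 + p.C * u**p.n
    if p.n == 1.0:
        dstress_du = -p.tauS * I * p.C / denom**2
    else:
        # u^(n-1) -> 0 as u -> 0+ for n > 1
        dstress_du = -p.tauS * I * p.C * p.n * u ** (p.n - 1.0) / denom**2 if u > 0 else 0.0
    J[2, 0] = dstress_du - p.r2 * m
    J[2, 2] = -p.d - p.r2 * u - 2.0 * p.r1 * m
    J[2, 4] = p.tauS / denom
    # d(dM)/d(u, M); growth term alpha1*u/(1+alpha2*u)*(Mhat-M)*M
    g = p.alpha1 * u / (1.0 + p.alpha2 * u)
    dg_du = p.alpha1 / (1.0 + p.alpha2 * u) ** 2
    J[3, 0] = dg_du * (p.Mhat - M) * M
    J[3, 3] = g * (p.Mhat - 2.0 * M) - p.sigma
    # d(dI)/d(u, M, I); source term tau1*u/(1+tau2*u)*M
    h = p.tau1 * u / (1.0 + p.tau2 * u)
    dh_du = p.tau1 / (1.0 + p.tau2 * u) ** 2
    J[4, 0] = dh_du * M
    J[4, 3] = h
    J[4, 4] = -p.tau3
    return J


def classify(e: Equilibrium, p: ModelParameters, *, tol: float = STABILITY_TOL) -> StabilityReport:
    """Eigenvalue-based stability label for an equilibrium."""
    eigenvalues = eig(jacobian(e.state, p), right=False)
    max_real = float(np.max(eigenvalues.real))
    if max_real < -tol:
        label = "stable"
    elif max_real > tol:
        label = "unstable"
    else:
        label = "marginal"
    return StabilityReport(eigenvalues=eigenvalues, max_real_part=max_real, label=label)
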