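"""Steady-state enumeration via the scalar reduction to the monomer axis.

At a stationary point every component is an explicit function of the
monomer concentration ``m``: u = rho·m², up = (r1/taup)·m², M solves a
quadratic in u, and I follows from the interleukin balance.  Substituting
back into the monomer equation leaves the scalar condition

    F(m) = P(m) + d,

with P the polymerization sink and F the inflammation-driven source per
unit monomer.  Positive equilibria are roots of G(m) = F(m) - P(m) - d;
the largest d admitting a positive root is ``critical_d``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model_core import ModelParameters, State, disease_free_state, rhs

__all__ = [
    "Equilibrium",
    "M_of_u",
    "reduce_from_m",
    "P_of_m",
    "F_of_m",
    "persistence_condition",
    "find_steady_states",
    "critical_d",
]

logger = logging.getLogger(__name__)

#: log-spaced scan grid used for bracketing roots and the maximum of F - P
_GRID_POINTS = 2000
_M_MIN = 1e-8
_ROOT_RTOL = 1e-10


@dataclass(frozen=True)
class Equilibrium:
    """A stationary point with its provenance on the monomer axis."""

    state: State
    kind: str  # "disease-free" | "positive"
    m_root: float | None = None  # monomer value solving the scalar equation
    marginal: bool = False  # double root at the fold (tangency)

    def residual(self, p: ModelParameters) -> float:
        return float(np.max(np.abs(rhs(self.state, p))))


def M_of_u(u: float, p: ModelParameters) -> float:
    """Positive root of the stationary microglial quadratic, as a function of u.

    The quadratic  a·M² + (sigma - a·Mhat)·M - lambdaM = 0  with
    a = alpha1·u/(1+alpha2·u) is evaluated through the rationalized form

        M = 2·lambdaM·(1 + alpha2·u) / (sqrt(D) + sigma + (sigma·alpha2 - Mhat·alpha1)·u),

    which is algebraically identical to the quadratic formula but finite at
    u = 0, where it reduces to lambdaM/sigma.
    """
    u = np.asarray(u, dtype=float)
    b = p.sigma * p.alpha2 - p.Mhat * p.alpha1
    disc = (p.sigma + b * u) ** 2 + 4.0 * p.lambdaM * p.alpha1 * u * (1.0 + p.alpha2 * u)
    result = 2.0 * p.lambdaM * (1.0 + p.alpha2 * u) / (np.sqrt(disc) + p.sigma + b * u)
    return float(result) if result.ndim == 0 else result


def reduce_from_m(m: float, p: ModelParameters) -> State:
    """Full stationary state generated by a monomer concentration m >= 0."""
    if m < 0:
        raise ValueError(f"m must be non-negative, got {m!r}")
    u = p.rho * m**2
    up = (p.r1 / p.taup) * m**2
    M = M_of_u(u, p)
    I = (p.tau1 / p.tau3) * u / (1.0 + p.tau2 * u) * M
    return State(u, up, m, M, I)


def P_of_m(m: float, p: ModelParameters) -> float:
    """Polymerization loss rate per unit monomer: r2·rho·m² + r1·m."""
    m = np.asarray(m, dtype=float)
    result = p.r2 * p.rho * m**2 + p.r1 * m
    return float(result) if result.ndim == 0 else result


def F_of_m(m: float, p: ModelParameters) -> float:
    """Stress-gated inflammation source per unit monomer.

    Closed form obtained by chaining u = rho·m², the microglial root and the
    interleukin balance through the production term; vanishes at m = 0 and
    decays as m -> infinity.
    """
    m = np.asarray(m, dtype=float)
    u = p.rho * m**2
    b = p.sigma * p.alpha2 - p.Mhat * p.alpha1
    disc = (p.sigma + b * u) ** 2 + 4.0 * p.lambdaM * p.alpha1 * u * (1.0 + p.alpha2 * u)
    numer = 2.0 * p.tau1 * p.tauS * p.lambdaM / p.tau3 * p.rho * m * (1.0 + p.alpha2 * u)
    denom = (np.sqrt(disc) + p.sigma + b * u) * (1.0 + p.tau2 * u) * (1.0 + p.C * u**p.n)
    result = numer / denom
    return float(result) if result.ndim == 0 else result


def persistence_condition(p: ModelParameters) -> bool:
    """True iff sigma·gamma0·tau3 < tau1·tauS·lambdaM (strict).

    Equivalent to F'(0) > 0 = P'(0) margin: the inflammation loop outgrows
    the polymerization sink near the disease-free point, so positive
    equilibria exist for small d.
    """
    return p.sigma * p.gamma0 * p.tau3 < p.tau1 * p.tauS * p.lambdaM


def _scan_grid(p: ModelParameters) -> np.ndarray:
    """Log grid over (0, m_max] with m_max the smallest power of 10 beyond
    which P dominates F everywhere (P > 2·max F), guaranteeing G < 0."""
    m_max = 1.0
    for _ in range(12):
        grid = np.logspace(np.log10(_M_MIN), np.log10(m_max), _GRID_POINTS)
        f_max = float(np.max(F_of_m(grid, p)))
        if P_of_m(m_max, p) > 2.0 * f_max:
            return grid
        m_max *= 10.0
    raise RuntimeError("could not find m_max with P(m_max) > 2 max F")


def find_steady_states(p: ModelParameters, *, residual_tol: float = 1e-8) -> list[Equilibrium]:
    """All non-negative equilibria, disease-free first, then sorted by m.

    Positive roots of G(m) = F(m) - P(m) - d are bracketed on a log grid
    and refined by Brent's method to relative tolerance 1e-10.  A tangency
    (double root at the fold) is reported once, flagged ``marginal``.
    """
    grid = _scan_grid(p)
    g = F_of_m(grid, p) - P_of_m(grid, p) - p.d

    roots: list[float] = []
    sign = np.sign(g)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        try:
            root = brentq(
                lambda m: F_of_m(m, p) - P_of_m(m, p) - p.d,
                lo, hi, rtol=_ROOT_RTOL,
            )
        except ValueError as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"failed to bracket root in [{lo:.6g}, {hi:.6g}]; "
                f"G values {g[i]:.6g}, {g[i + 1]:.6g}"
            ) from exc
        roots.append(float(root))
    # exact zeros on grid nodes (measure-zero but cheap to honour)
    roots.extend(float(grid[i]) for i in np.nonzero(g == 0.0)[0])
    roots = sorted(set(roots))

    marginal = False
    if not roots and persistence_condition(p):
        # possible tangency: G may touch zero at its maximum without a sign change
        i_best = int(np.argmax(g))
        res = minimize_scalar(
            lambda m: -(F_of_m(m, p) - P_of_m(m, p)),
            bounds=(grid[max(i_best - 1, 0)], grid[min(i_best + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if abs(-res.fun - p.d) < 1e-9:
            roots = [float(res.x)]
            marginal = True

    out = [Equilibrium(disease_free_state(p), "disease-free")]
    for m in roots:
        eq = Equilibrium(reduce_from_m(m, p), "positive", m_root=m, marginal=marginal)
        res = eq.residual(p)
        if res > residual_tol:
            logger.warning("equilibrium at m=%.6g has residual %.3g", m, res)
        out.append(eq)
    logger.debug("found %d equilibria (d=%.6g): m roots %s", len(out), p.d, roots)
    return out


def critical_d(p: ModelParameters) -> float:
    """Largest monomer degradation rate admitting positive equilibria.

    Equals max over m > 0 of F(m) - P(m); located by a coarse log-grid
    scan followed by bounded scalar maximization.  Returns 0 when the
    persistence condition fails (F - P <= 0 near the origin and the
    maximum is irrelevant).
    """
    if not persistence_condition(p):
        return 0.0
    grid = _scan_grid(p)
    g = F_of_m(grid, p) - P_of_m(grid, p)
    i = int(np.argmax(g))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda m: -(F_of_m(m, p) - P_of_m(m, p)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10},
    )
    value = float(-res.fun)
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite maximum of F - P near m={res.x!r}")
    return max(value, 0.0)
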