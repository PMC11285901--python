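"""Bifurcation branch tracing in d and critical-initial-condition maps.

For d below the fold value the system is bistable: the outcome depends on
where the initial condition sits relative to a separatrix.  This module
traces the equilibrium branches over a d grid, bisects the initial
inflammation (or monomer) level to locate the basin boundary, and rasterizes
outcome labels over a (d, x0) grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import OUTCOME_DISEASE_FREE, OUTCOME_PERSISTENT, classify_outcome
from .equilibria import Equilibrium, critical_d, find_steady_states
from .model_core import ModelParameters, State
from .stability import StabilityReport, classify

__all__ = [
    "BifurcationRow",
    "BifurcationBranch",
    "ThresholdCurve",
    "sweep_bifurcation",
    "critical_initial",
    "threshold_curve",
    "basin_map",
]

logger = logging.getLogger(__name__)

AXES = ("I0", "m0")
#: axis name -> State field varied by critical_initial / basin_map
_AXIS_FIELD = {"I0": "I", "m0": "m"}

BISECT_TOL = 1e-3  # mol/l, absolute, on the varied initial component
DOUBLING_CAP = 1024.0  # give up the upward search for a persistent outcome here


@dataclass(frozen=True)
class BifurcationRow:
    d: float
    equilibrium: Equilibrium
    stability: StabilityReport


@dataclass(frozen=True)
class BifurcationBranch:
    rows: list[BifurcationRow]

    def at(self, d: float) -> list[BifurcationRow]:
        return [r for r in self.rows if r.d == d]


@dataclass(frozen=True)
class ThresholdCurve:
    axis: str  # "I0" | "m0"
    d_values: np.ndarray
    critical_values: list[float | None]  # None where d >= critical d


def sweep_bifurcation(d_grid: np.ndarray, p: ModelParameters) -> BifurcationBranch:
    """Equilibria and their stability at every d in an increasing grid."""
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(d_grid <= 0) or np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be positive and strictly increasing")
    rows: list[BifurcationRow] = []
    for d in d_grid:
        pd = p.replace(d=float(d))
        equilibria = find_steady_states(pd)
        for eq in equilibria:
            rows.append(BifurcationRow(float(d), eq, classify(eq, pd)))
        logger.info("bifurcation column d=%.4g: %d equilibria", d, len(equilibria))
    return BifurcationBranch(rows)


def _with_axis(base_init: State, axis: str, value: float) -> State:
    return base_init.replace(**{_AXIS_FIELD[axis]: float(value)})


def critical_initial(
    d: float,
    axis: str,
    p: ModelParameters,
    base_init: State,
    *,
    tol: float = BISECT_TOL,
) -> float | None:
    """Basin-boundary value of the varied initial component at one d.

    Bisects between a disease-free outcome below and a persistent outcome
    above; the upper bracket is found by doubling from 1 (capped at 2¹⁰).
    Returns None when d is at or beyond the fold (no persistent attractor)
    or when no persistent outcome is found below the cap.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    pd = p.replace(d=float(d))
    if d >= critical_d(pd):
        return None
    equilibria = find_steady_states(pd)

    def outcome(x: float) -> str:
        return classify_outcome(_with_axis(base_init, axis, x), pd, equilibria=equilibria)

    lo = 0.0
    if outcome(lo) != OUTCOME_DISEASE_FREE:
        logger.warning("outcome at %s=0 is not disease-free for d=%.4g", axis, d)
        return None
    hi = 1.0
    while outcome(hi) != OUTCOME_PERSISTENT:
        hi *= 2.0
        if hi > DOUBLING_CAP:
            logger.warning(
                "no persistent outcome found for %s up to %g at d=%.4g "
                "(possible undecided band)", axis, DOUBLING_CAP, d,
            )
            return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid) == OUTCOME_DISEASE_FREE:
            lo = mid
        else:  # persistent or undecided: the separatrix is at or below mid
            hi = mid
    return 0.5 * (lo + hi)


def threshold_curve(
    d_grid: np.ndarray,
    axis: str,
    p: ModelParameters,
    base_init: State,
    *,
    tol: float = BISECT_TOL,
) -> ThresholdCurve:
    """critical_initial swept over a d grid."""
    d_grid = np.asarray(d_grid, dtype=float)
    values = [critical_initial(float(d), axis, p, base_init, tol=tol) for d in d_grid]
    return ThresholdCurve(axis=axis, d_values=d_grid, critical_values=values)


def basin_map(
    d_grid: np.ndarray,
    x_grid: np.ndarray,
    axis: str,
    p: ModelParameters,
    base_init: State,
    *,
    validate_monotone: bool = False,
) -> np.ndarray:
    """Outcome labels on the (d, x0) grid; shape (len(d_grid), len(x_grid)).

    With ``validate_monotone`` every column is checked for a single
    disease-free -> persistent transition; violating columns are logged
    (bisection in :func:`critical_initial` assumes monotonicity).
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    d_grid = np.asarray(d_grid, dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)
    labels = np.empty((len(d_grid), len(x_grid)), dtype=object)
    for i, d in enumerate(d_grid):
        pd = p.replace(d=float(d))
        equilibria = find_steady_states(pd)
        for j, x in enumerate(x_grid):
            labels[i, j] = classify_outcome(
                _with_axis(base_init, axis, x), pd, equilibria=equilibria
            )
        logger.info("basin column d=%.4g done", d)
        if validate_monotone:
            col = labels[i]
            persistent = [k for k, v in enumerate(col) if v == OUTCOME_PERSISTENT]
            free = [k for k, v in enumerate(col) if v == OUTCOME_DISEASE_FREE]
            if persistent and free and max(free) > min(persistent):
                logger.warning("non-monotone outcome column at d=%.4g", d)
    return labels
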