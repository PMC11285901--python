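"""Time integration and asymptotic-outcome classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium, find_steady_states
from .model_core import ModelParameters, State, rhs

__all__ = ["Trajectory", "IntegrationError", "simulate", "classify_outcome"]

logger = logging.getLogger(__name__)

RTOL = 1e-8
ATOL = 1e-10
#: negative excursions smaller than this are solver noise and are clipped
CLIP = 1e-9
#: doubling horizons (months) tried before declaring the outcome undecided
HORIZONS = (2000.0, 4000.0, 8000.0)
#: Euclidean distance below which a final state is matched to an equilibrium
MATCH_DISTANCE = 1e-4

OUTCOME_DISEASE_FREE = "disease-free"
OUTCOME_PERSISTENT = "persistent"
OUTCOME_UNDECIDED = "undecided"


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class Trajectory:
    times: np.ndarray  # increasing, times[0] == 0
    states: np.ndarray  # shape (len(times), 5)
    outcome: str = OUTCOME_UNDECIDED

    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def component(self, name: str) -> np.ndarray:
        return self.states[:, State.FIELDS.index(name)]


def _integrate(y0: np.ndarray, p: ModelParameters, t_span: tuple[float, float],
               t_eval: np.ndarray | None, rtol: float, atol: float):
    sol = solve_ivp(
        lambda _t, y: rhs(y, p), t_span, y0,
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t_span[0]
        raise IntegrationError(f"integration failed at t={last:.6g}: {sol.message}", last)
    return sol


def simulate(init: State, p: ModelParameters, t_end: float, *,
             n_samples: int = 501, rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Solve the initial-value problem on [0, t_end] with a stiff-capable
    adaptive integrator, sampled on a uniform grid of ``n_samples`` times.

    States are clipped at -1e-9 to remove solver-level negative noise.
    """
    y0 = init.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    t_eval = np.linspace(0.0, t_end, max(n_samples, 501))
    sol = _integrate(y0, p, (0.0, t_end), t_eval, rtol, atol)
    states = sol.y.T.copy()
    if np.min(states) < -CLIP:
        logger.warning("trajectory dipped to %.3g below zero; clipping", np.min(states))
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=sol.t.copy(), states=states)


def classify_outcome(
    init: State,
    p: ModelParameters,
    *,
    equilibria: list[Equilibrium] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> str:
    """Label the long-run fate of an initial condition.

    Integrates over doubling horizons until the state lands within
    ``MATCH_DISTANCE`` (Euclidean, raw concentrations) of a known
    equilibrium.  Returns "disease-free", "persistent" or — if no horizon
    settles the question — "undecided" rather than a guess.
    """
    if equilibria is None:
        equilibria = find_steady_states(p)
    targets = [(eq.kind, eq.state.as_array()) for eq in equilibria]

    y = init.as_array().astype(float)
    t_done = 0.0
    for horizon in HORIZONS:
        sol = _integrate(y, p, (t_done, horizon), None, rtol, atol)
        y = np.clip(sol.y[:, -1], 0.0, None)
        t_done = horizon
        dists = [float(np.linalg.norm(y - target)) for _, target in targets]
        i = int(np.argmin(dists))
        if dists[i] < MATCH_DISTANCE:
            kind = targets[i][0]
            return OUTCOME_DISEASE_FREE if kind == "disease-free" else OUTCOME_PERSISTENT
    logger.info("outcome undecided after %.0f months from %s", t_done, init)
    return OUTCOME_UNDECIDED
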