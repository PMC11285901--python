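"""Core kinetic model: parameters, state and the homogeneous vector field.

The model couples five concentrations — free oligomers ``u``, plaque-bound
oligomers ``up``, monomers ``m``, microglia ``M`` and interleukins ``I`` —
through polymerization, plaque recruitment, a stress-gated production term
and an inflammation loop.  Time is measured in months, concentrations in
mol/l; no internal rescaling is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ModelParameters",
    "State",
    "stress_production",
    "recruitment_rate",
    "rhs",
    "disease_free_state",
]

# Parameters that must be strictly positive for the model to be well posed.
_STRICTLY_POSITIVE = ("d", "gamma0", "taup", "tau3", "sigma")


@dataclass(frozen=True)
class ModelParameters:
    """The rate constants of the homogeneous model.

    Units: second-order rates (``r1``, ``r2``, ``tau1``, ``alpha1``) are
    l·mol⁻¹·months⁻¹; first-order rates (``d``, ``gamma0``, ``tau0``,
    ``taup``, ``tauS``, ``tau3``, ``sigma``) are months⁻¹; ``lambdaM`` is
    mol·l⁻¹·months⁻¹; ``C`` is lⁿ·mol⁻ⁿ; ``n``, ``Mhat``, ``tau2``,
    ``alpha2``, ``gamma1``, ``gamma2`` complete the saturating terms.
    """

    r1: float  # bi-monomeric polymerization rate
    r2: float  # monomer-to-oligomer attachment rate
    d: float  # monomer degradation rate (bifurcation parameter)
    gamma0: float  # constant oligomer-to-plaque recruitment rate
    taup: float  # plaque-oligomer degradation rate
    tauS: float  # neural stress coefficient
    tau1: float  # interleukin growth coefficient
    tau2: float  # interleukin growth saturation
    tau3: float  # interleukin degradation rate
    C: float  # stress-function coefficient
    n: float  # stress-function power, >= 1
    alpha1: float  # microglial growth coefficient
    alpha2: float  # microglial growth saturation
    lambdaM: float  # microglial proliferation source
    Mhat: float  # microglial capacity
    sigma: float  # microglial degradation rate
    gamma1: float = 1.0  # Michaelis-Menten slope of the full recruitment rate
    gamma2: float = 1.0  # Michaelis-Menten saturation of the full rate
    tau0: float = 0.0  # free-oligomer degradation rate (default: negligible)

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {f.name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {f.name} must be non-negative, got {value!r}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.n < 1:
            raise ValueError(f"stress power n must be >= 1, got {self.n!r}")

    @property
    def rho(self) -> float:
        """Steady-state ratio u/m² = r1/gamma0."""
        return self.r1 / self.gamma0

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass(frozen=True)
class State:
    """Concentrations (mol/l) of the five species at one instant."""

    u: float  # free oligomers
    up: float  # oligomers in amyloid plaques
    m: float  # monomers
    M: float  # microglial cells
    I: float  # interleukins

    FIELDS = ("u", "up", "m", "M", "I")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.up, self.m, self.M, self.I], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        y = np.asarray(y, dtype=float)
        if y.shape != (5,):
            raise ValueError(f"state vector must have shape (5,), got {y.shape}")
        return cls(*map(float, y))

    def replace(self, **changes: float) -> "State":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.FIELDS}

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_array())


def disease_free_state(p: ModelParameters) -> State:
    """The always-present equilibrium (0, 0, 0, lambdaM/sigma, 0)."""
    return State(0.0, 0.0, 0.0, p.lambdaM / p.sigma, 0.0)


def stress_production(u: float, I: float, p: ModelParameters) -> float:
    """Monomer production rate tauS·I/(1 + C·uⁿ).

    Interleukins drive production linearly; a high oligomer load shuts it
    down (unfolded-protein-response stress).
    """
    u = np.asarray(u, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(u < 0) or np.any(I < 0):
        raise ValueError("stress_production requires u >= 0 and I >= 0")
    result = p.tauS * I / (1.0 + p.C * u**p.n)
    return float(result) if result.ndim == 0 else result


def recruitment_rate(M: float, p: ModelParameters) -> float:
    """Full plaque-recruitment rate gamma0 + gamma1·M/(1 + gamma2·M).

    Provided for completeness; the homogeneous vector field uses the
    constant ``gamma0``.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("recruitment_rate requires M >= 0")
    result = p.gamma0 + p.gamma1 * M / (1.0 + p.gamma2 * M)
    return float(result) if result.ndim == 0 else result


def rhs(s: State | np.ndarray, p: ModelParameters) -> np.ndarray:
    """Time derivatives (du, dup, dm, dM, dI) of the homogeneous system."""
    y = s.as_array() if isinstance(s, State) else np.asarray(s, dtype=float)
    if y.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y}")
    u, up, m, M, I = y
    du = p.r1 * m**2 - p.gamma0 * u - p.tau0 * u
    dup = p.gamma0 * u - p.taup * up
    dm = p.tauS * I / (1.0 + p.C * u**p.n) - p.d * m - p.r2 * u * m - p.r1 * m**2
    dM = p.alpha1 * u / (1.0 + p.alpha2 * u) * (p.Mhat - M) * M - p.sigma * M + p.lambdaM
    dI = p.tau1 * u / (1.0 + p.tau2 * u) * M - p.tau3 * I
    return np.array([du, dup, dm, dM, dI])
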