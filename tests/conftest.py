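import numpy as np
import pytest

from admodel.cli_io import resolve_initial, resolve_parameters
from admodel.model_core import ModelParameters, State


@pytest.fixture
def table2():
    """Factory: default parameter preset with a chosen degradation rate d."""

    def make(d: float = 0.15, **overrides) -> ModelParameters:
        return resolve_parameters("table2", {**{"d": d}, **overrides})

    return make


@pytest.fixture
def table3_init():
    """Factory: default initial condition varying the interleukin level I0."""

    def make(I0: float) -> State:
        return resolve_initial("table3", {"I": I0})

    return make


@pytest.fixture
def table4_init():
    """Factory: default initial condition varying the monomer level m0."""

    def make(m0: float) -> State:
        return resolve_initial("table4", {"m": m0})

    return make


def random_positive_parameters(rng: np.random.Generator) -> ModelParameters:
    """A random valid parameter set, rates log-uniform in [1e-3, 10]."""

    def draw() -> float:
        return float(10.0 ** rng.uniform(-3, 1))

    return ModelParameters(
        r1=draw(), r2=draw(), d=draw(), gamma0=draw(), taup=draw(),
        tauS=draw(), tau1=draw(), tau2=draw(), tau3=draw(), C=draw(),
        n=float(rng.uniform(1.0, 4.0)), alpha1=draw(), alpha2=draw(),
        lambdaM=draw(), Mhat=draw(), sigma=draw(), tau0=float(rng.uniform(0, 0.1)),
    )
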