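import numpy as np
import pytest

from admodel.equilibria import (
    F_of_m,
    M_of_u,
    P_of_m,
    critical_d,
    find_steady_states,
    persistence_condition,
    reduce_from_m,
)
from admodel.model_core import disease_free_state, rhs, stress_production


def quadratic_root_oracle(u, p):
    """Brute-force positive root of a*M^2 + (sigma - a*Mhat)*M - lambdaM = 0."""
    a = p.alpha1 * u / (1.0 + p.alpha2 * u)
    if a == 0.0:
        return p.lambdaM / p.sigma
    roots = np.roots([a, p.sigma - a * p.Mhat, -p.lambdaM])
    positive = roots[np.isreal(roots) & (roots.real > 0)].real
    assert len(positive) == 1
    return float(positive[0])


class TestMicroglialRoot:
    def test_baseline(self, table2):
        # lambdaM/sigma = 1e-3/1e-3
        assert M_of_u(0.0, table2(0.15)) == pytest.approx(1.0)

    @pytest.mark.parametrize("u", [1e-6, 1e-3, 0.1, 1.0, 1e3])
    def test_residual_of_defining_equation(self, table2, u):
        p = table2(0.15)
        M = M_of_u(u, p)
        residual = p.alpha1 * u / (1 + p.alpha2 * u) * (p.Mhat - M) * M - p.sigma * M + p.lambdaM
        assert abs(residual) < 1e-10

    @pytest.mark.parametrize("u", [1e-6, 1.0, 1e3])
    def test_against_quadratic_oracle(self, table2, u):
        p = table2(0.15)
        assert M_of_u(u, p) == pytest.approx(quadratic_root_oracle(u, p), rel=1e-8)

    def test_continuous_at_zero(self, table2):
        p = table2(0.15)
        assert M_of_u(1e-14, p) == pytest.approx(M_of_u(0.0, p), rel=1e-10)

    def test_oracle_on_random_parameters(self):
        from conftest import random_positive_parameters

        rng = np.random.default_rng(11)
        for _ in range(30):
            p = random_positive_parameters(rng)
            u = float(10.0 ** rng.uniform(-6, 3))
            assert M_of_u(u, p) == pytest.approx(quadratic_root_oracle(u, p), rel=1e-8)


class TestReduction:
    def test_zero_monomer_gives_disease_free(self, table2):
        p = table2(0.15)
        s = reduce_from_m(0.0, p)
        assert s == disease_free_state(p)
        assert s.M == pytest.approx(1.0)

    def test_oligomer_component(self, table2):
        # u = rho m^2 with rho = 0.1/0.05 = 2
        assert reduce_from_m(0.1, table2(0.15)).u == pytest.approx(0.02)

    def test_plaque_component(self, table2):
        p = table2(0.15)
        assert reduce_from_m(0.1, p).up == pytest.approx(p.r1 / p.taup * 0.01)

    def test_rejects_negative(self, table2):
        with pytest.raises(ValueError):
            reduce_from_m(-0.1, table2(0.15))

    @pytest.mark.parametrize("m", [0.01, 0.1, 1.0])
    def test_stationary_except_monomer_equation(self, table2, m):
        # every equation other than the monomer one is annihilated by design
        p = table2(0.15)
        out = rhs(reduce_from_m(m, p), p)
        assert np.max(np.abs(out[[0, 1, 3, 4]])) < 1e-12


class TestScalarFunctions:
    def test_P_at_zero(self, table2):
        assert P_of_m(0.0, table2(0.15)) == 0.0

    def test_P_hand_value(self, table2):
        # 0.1*2*m^2 + 0.1*m at m = 0.5
        assert P_of_m(0.5, table2(0.15)) == pytest.approx(0.2 * 0.25 + 0.05)

    def test_P_monotone(self, table2):
        m = np.linspace(0, 10, 1000)
        assert np.all(np.diff(P_of_m(m, table2(0.15))) > 0)

    def test_F_at_zero(self, table2):
        assert F_of_m(0.0, table2(0.15)) == 0.0

    def test_F_slope_at_zero(self, table2):
        # closed form r1*tau1*tauS*lambdaM/(sigma*gamma0*tau3) = 2.0
        h = 1e-6
        p = table2(0.15)
        slope = (F_of_m(h, p) - F_of_m(-0.0, p)) / h
        assert slope == pytest.approx(2.0, rel=1e-4)
        closed = p.r1 * p.tau1 * p.tauS * p.lambdaM / (p.sigma * p.gamma0 * p.tau3)
        assert closed == pytest.approx(2.0)

    def test_F_positive_and_decaying(self, table2):
        p = table2(0.15)
        m = np.logspace(-6, 2, 200)
        assert np.all(F_of_m(m, p) > 0)
        assert F_of_m(1e6, p) < 1e-12

    @pytest.mark.parametrize("m", [0.01, 0.1, 1.0])
    def test_F_matches_reduction_composition(self, table2, m):
        # independent route: F = stress(u, I)/m through the full reduction
        p = table2(0.15)
        s = reduce_from_m(m, p)
        oracle = stress_production(s.u, s.I, p) / m
        assert F_of_m(m, p) == pytest.approx(oracle, rel=1e-12)

    def test_F_matches_reduction_on_random_parameters(self):
        from conftest import random_positive_parameters

        rng = np.random.default_rng(3)
        for _ in range(30):
            p = random_positive_parameters(rng)
            m = float(10.0 ** rng.uniform(-3, 1))
            s = reduce_from_m(m, p)
            oracle = stress_production(s.u, s.I, p) / m
            assert F_of_m(m, p) == pytest.approx(oracle, rel=1e-10)


class TestPersistenceCondition:
    def test_default_parameters_persist(self, table2):
        # 1e-3 * 0.05 * 1 < 1 * 1 * 1e-3
        assert persistence_condition(table2(0.15))

    def test_fast_microglial_turnover_blocks(self, table2):
        assert not persistence_condition(table2(0.15, sigma=0.1))

    def test_equality_is_false(self, table2):
        # tauS = sigma*gamma0*tau3/(tau1*lambdaM) makes both sides equal
        p = table2(0.15, tauS=0.05)
        assert p.sigma * p.gamma0 * p.tau3 == p.tau1 * p.tauS * p.lambdaM
        assert not persistence_condition(p)


class TestFindSteadyStates:
    @pytest.mark.parametrize("d,count", [(0.15, 3), (0.35, 3), (0.55, 1)])
    def test_equilibrium_counts(self, table2, d, count):
        assert len(find_steady_states(table2(d))) == count

    def test_sorted_disease_free_first(self, table2):
        eqs = find_steady_states(table2(0.15))
        assert eqs[0].kind == "disease-free"
        ms = [e.m_root for e in eqs[1:]]
        assert ms == sorted(ms)

    def test_residuals(self, table2):
        p = table2(0.15)
        for eq in find_steady_states(p):
            assert eq.residual(p) < 1e-8

    def test_positive_components(self, table2):
        p = table2(0.35)
        for eq in find_steady_states(p):
            if eq.kind == "positive":
                assert np.all(eq.state.as_array() > 0)

    def test_no_positive_under_weak_stress(self, table2):
        eqs = find_steady_states(table2(0.15, tauS=0.01))
        assert len(eqs) == 1 and eqs[0].kind == "disease-free"

    def test_persistence_condition_is_sufficient_not_necessary(self, table2):
        # fast microglial turnover breaks the condition (small-d guarantee)
        # yet a pair of positive equilibria survives away from the origin
        p = table2(0.15, sigma=0.1)
        assert not persistence_condition(p)
        assert sum(e.kind == "positive" for e in find_steady_states(p)) == 2

    def test_at_fold_does_not_crash(self, table2):
        dc = critical_d(table2(0.15))
        eqs = find_steady_states(table2(dc))
        assert len(eqs) in (1, 2, 3)  # tangency may resolve either way numerically


class TestCriticalD:
    def test_default_parameters(self, table2):
        assert critical_d(table2(0.15)) == pytest.approx(0.4779, abs=1e-3)

    def test_zero_without_persistence(self, table2):
        assert critical_d(table2(0.15, sigma=0.1)) == 0.0

    def test_zero_without_microglial_source(self, table2):
        assert critical_d(table2(0.15, lambdaM=0.0)) == 0.0

    def test_brackets_positive_equilibria(self, table2):
        dc = critical_d(table2(0.15))
        below = find_steady_states(table2(dc - 1e-3))
        above = find_steady_states(table2(dc + 1e-3))
        assert sum(e.kind == "positive" for e in below) >= 2
        assert sum(e.kind == "positive" for e in above) == 0

    def test_is_max_of_gap(self, table2):
        p = table2(0.15)
        dc = critical_d(p)
        m = np.logspace(-8, 1, 5000)
        assert dc >= np.max(F_of_m(m, p) - P_of_m(m, p)) - 1e-10
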