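import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import evofit as ef
from evofit.delay import (
    DelayModel,
    change_of_variables_check,
    char_matrix,
    characteristic_roots,
    delay_fitness,
    foerster_to_delay,
    simulate_dde,
    total_density_limitation,
    validate_root,
)
from evofit.stage import StageModel, build_stage_matrix, dominant_eigenvalue, stage_fitness


def scalar_model(q=1.0, tau=1.0, r=0.0, R=1.0, f=None, grid=None):
    return DelayModel(n=1, tau=[tau], q=np.array([[[q]]]), r=np.array([[r]]),
                      R=R, grid=grid, f=f)


HAIRY_ROOT = brentq(lambda x: x - np.exp(-x), 0.0, 1.0, xtol=1e-15)  # lambda = e^-lambda


class TestCharMatrix:
    def test_no_delays_gives_a_constant_matrix(self):
        m = DelayModel(n=2, tau=[1.0], q=np.zeros((2, 2, 1)),
                       r=np.array([[1.0, 2.0], [3.0, 4.0]]))
        # q = 0: H does not depend on lambda
        assert np.allclose(char_matrix(m, 0.0, 0.0), char_matrix(m, 0.0, 5.0))

    def test_scalar_at_zero(self):
        assert char_matrix(scalar_model(), 0.0, 0.0)[0, 0] == pytest.approx(1.0)

    def test_scalar_exponential_decay_of_the_delayed_weight(self):
        assert char_matrix(scalar_model(), 0.0, np.log(2.0))[0, 0] == pytest.approx(0.5)


class TestCharacteristicRoots:
    def test_scalar_hairy_root(self):
        rs = characteristic_roots(scalar_model())
        assert rs.rightmost.real == pytest.approx(HAIRY_ROOT, abs=1e-10)
        assert abs(rs.rightmost.imag) < 1e-12

    def test_vanishing_delay_recovers_the_ode_rate(self):
        rs = characteristic_roots(scalar_model(q=2.0, tau=1e-12))
        assert rs.rightmost.real == pytest.approx(2.0, abs=1e-6)

    def test_delay_free_matrix_case_matches_the_eigensolver(self):
        L = np.array([[-1.1, 2.0], [1.0, -0.2]])
        m = DelayModel(n=2, tau=[1.0], q=np.zeros((2, 2, 1)), r=L)
        rs = characteristic_roots(m)
        assert rs.rightmost.real == pytest.approx(
            dominant_eigenvalue(L).lambda1, abs=1e-10
        )

    def test_residual_contract_for_every_reported_root(self):
        rs = characteristic_roots(scalar_model())
        assert np.all(rs.residuals < 1e-10)

    def test_conjugate_symmetry_for_real_coefficients(self):
        rs = characteristic_roots(scalar_model())
        cplx = rs.roots[np.abs(rs.roots.imag) > 1e-9]
        assert cplx.size >= 2
        for z in cplx:
            assert np.min(np.abs(rs.roots - z.conjugate())) < 1e-8

    def test_seeded_exponential_solution_satisfies_the_linear_dde(self):
        m = scalar_model()
        for z in characteristic_roots(m).roots[:3]:
            assert validate_root(m, 0.0, z) < 1e-8


class TestDelayFitness:
    def test_more_reproduction_means_higher_fitness(self):
        grid = ef.StrategyGrid.atoms([0.0, 1.0])
        m = DelayModel(n=1, tau=[1.0], q=lambda v: np.array([[[1.0 + v]]]),
                       r=np.zeros((1, 1)), grid=grid)
        scape = delay_fitness(m)
        assert scape.J[1] > scape.J[0]
        # bisection oracle for the real root of lambda = q e^{-lambda}
        for q, J in zip((1.0, 2.0), scape.J):
            oracle = brentq(lambda x: x - q * np.exp(-x), 0.0, q + 1.0)
            assert J == pytest.approx(oracle, abs=1e-9)

    def test_rescaling_R_rescales_fitness_inversely(self):
        base = delay_fitness(scalar_model(R=1.0)).J[0]
        assert delay_fitness(scalar_model(R=2.0)).J[0] == pytest.approx(base / 2.0)

    def test_delay_free_embedding_reproduces_the_stage_landscape(self):
        grid = ef.StrategyGrid.uniform(11)
        sm = StageModel(n=2, b=lambda v: np.array([0.0, 2.0 + v]), a=[0.1, 0.2],
                        p=[1.0, 0.0], R=lambda v: 1.0 + 0.5 * v, grid=grid)
        dm = DelayModel(
            n=2, tau=[1.0], q=np.zeros((2, 2, 1)),
            r=lambda v: build_stage_matrix(sm, v),
            R=lambda v: 1.0 + 0.5 * v, grid=grid,
        )
        assert np.max(np.abs(delay_fitness(dm).J - stage_fitness(sm).J)) < 1e-6


class TestSimulateDDE:
    def test_delay_free_limit_matches_an_ode_solver(self):
        m = DelayModel(n=1, tau=[1.0], q=np.zeros((1, 1, 1)), r=np.array([[-0.3]]))
        traj = simulate_dde(m, 10.0, rtol=1e-10, atol=1e-12)
        sol = solve_ivp(lambda t, z: -0.3 * z, (0, 10.0), [1.0], rtol=1e-12,
                        atol=1e-14, dense_output=True)
        diff = traj.z[0, 0, :] - sol.sol(traj.times)[0]
        assert np.max(np.abs(diff)) < 1e-8

    def test_linear_growth_rate_matches_the_rightmost_root(self):
        traj = simulate_dde(scalar_model(), 60.0)
        Z = traj.total_density()[0]
        i = np.searchsorted(traj.times, 30.0)
        slope = (np.log(Z[-1]) - np.log(Z[i])) / (traj.times[-1] - traj.times[i])
        assert slope == pytest.approx(HAIRY_ROOT, abs=1e-5)

    def test_zero_history_stays_zero(self):
        m = DelayModel(n=1, tau=[0.5], q=np.array([[[1.0]]]), r=np.array([[0.2]]),
                       history=lambda v, t: np.zeros(1))
        traj = simulate_dde(m, 5.0)
        assert np.all(traj.z == 0.0)

    def test_nonnegative_coefficients_keep_the_state_nonnegative(self):
        m = scalar_model(q=0.8, r=-0.5, f=total_density_limitation)
        traj = simulate_dde(m, 30.0)
        assert np.all(traj.z >= -1e-12)


class TestChangeOfVariables:
    def test_inactive_limitation_gives_zero_deviation(self):
        m = scalar_model(f=lambda z, g, t: 0.0)
        assert change_of_variables_check(m, 20.0) < 1e-9

    def test_logistic_limitation_single_strategy(self):
        m = scalar_model(f=total_density_limitation)
        assert change_of_variables_check(m, 50.0) < 1e-5

    def test_two_strategy_competition(self):
        grid = ef.StrategyGrid.atoms([0.0, 1.0])
        m = DelayModel(n=1, tau=[0.8], q=lambda v: np.array([[[1.0 + 0.5 * v]]]),
                       r=lambda v: np.array([[-0.2]]), R=lambda v: 1.0 + v,
                       grid=grid, f=total_density_limitation)
        assert change_of_variables_check(m, 50.0) < 1e-5


class TestFoersterReduction:
    def test_printed_survival_coefficient(self):
        dm = foerster_to_delay([1.0], a=[0.1, 0.2], b=[0.0, 2.0])
        q = dm.q_values(0.0)
        assert q[1, 1, 0] == pytest.approx(2.0 * np.exp(-0.1))

    def test_zero_mortality_gives_unit_survival(self):
        dm = foerster_to_delay([1.0, 2.0], a=[0.0, 0.0, 0.0], b=[0.0, 1.5, 2.5])
        q = dm.q_values(0.0)
        assert np.allclose(q[1, :, 0], [0.0, 1.5, 2.5])  # inflow of stage 2
        assert np.allclose(q[0, :, 0], [0.0, -1.5, -2.5])  # outflow of stage 1
        assert np.allclose(q[2, :, 1], [0.0, 1.5, 2.5])  # inflow of the last stage
        # last stage has no outflow term
        assert np.allclose(q[2, :, 0], 0.0) and np.allclose(q[1, :, 1], [0.0, -1.5, -2.5])

    def test_mortalities_sit_on_the_diagonal(self):
        dm = foerster_to_delay([1.0], a=[0.1, 0.2], b=[0.0, 2.0])
        r = dm.r_values(0.0)
        assert np.allclose(np.diag(r), [-0.1, -0.2])
        assert r[0, 1] == 2.0  # undelayed newborn inflow into stage 1

    def test_dominant_root_matches_the_euler_lotka_oracle(self):
        # independent oracle: 1 = int b(tau) e^{-lambda tau} survival(tau) dtau
        a1, a2, b2, tau1 = 0.1, 0.2, 2.0, 1.0
        oracle = brentq(
            lambda lam: lam + a2 - b2 * np.exp(-a1 * tau1) * np.exp(-lam * tau1),
            0.0, 3.0, xtol=1e-14,
        )
        dm = foerster_to_delay([tau1], a=[a1, a2], b=[0.0, b2])
        assert characteristic_roots(dm).rightmost.real == pytest.approx(oracle, abs=1e-10)

    def test_three_stage_root_matches_euler_lotka(self):
        a, b, ages = [0.2, 0.1, 0.3], [0.0, 1.2, 2.0], [0.8, 2.0]

        def euler_lotka(lam):
            # survival to age tau with piecewise-constant mortality
            s1 = np.exp(-a[0] * ages[0])
            s2 = s1 * np.exp(-a[1] * (ages[1] - ages[0]))
            term2 = b[1] * s1 * (
                np.exp(-(lam + a[1]) * 0.0) - np.exp(-(lam + a[1]) * (ages[1] - ages[0]))
            ) / (lam + a[1]) * np.exp(-lam * ages[0])
            term3 = b[2] * s2 * np.exp(-lam * ages[1]) / (lam + a[2])
            return 1.0 - term2 - term3

        oracle = brentq(euler_lotka, 0.01, 3.0, xtol=1e-14)
        dm = foerster_to_delay(ages, a=a, b=b)
        assert characteristic_roots(dm).rightmost.real == pytest.approx(oracle, abs=1e-9)

    def test_simulated_cohorts_stay_nonnegative(self):
        dm = foerster_to_delay([1.0], a=[0.1, 0.2], b=[0.0, 2.0],
                               f=total_density_limitation)
        traj = simulate_dde(dm, 40.0)
        assert np.all(traj.z > -1e-9)

    def test_decreasing_age_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            foerster_to_delay([2.0, 1.0], a=[0.1, 0.1, 0.1], b=[0.0, 1.0, 1.0])


class TestWinnerPrediction:
    def test_fitness_gap_predicts_the_simulated_survivor(self):
        from evofit.synthetic import two_strategy_delay_contest

        model, Jw, Jl, winner = two_strategy_delay_contest(3)
        traj = simulate_dde(model, 200.0, n_out=101)
        eta = traj.eta_field()
        iw = eta.grid.index_of(winner)
        il = 1 - iw
        assert eta.values[il, -1] / eta.values[iw, -1] < 1e-3
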