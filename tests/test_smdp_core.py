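import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import simpson
from scipy.optimize import brentq

from laborleisure import leisure_utility as lu
from laborleisure import smdp_core as sc


def trunc_exp_mean(rate, tau_max):
    """Independent closed form: mean of exp(-rate*tau) density on
    [0, tau_max]."""
    if abs(rate * tau_max) < 1e-12:
        return tau_max / 2.0
    return 1.0 / rate - tau_max / math.expm1(min(rate * tau_max, 700.0))


# ---------------------------------------------------------------------------
# Q-values
# ---------------------------------------------------------------------------


class TestQValues:
    def test_leisure_zero_duration_returns_pre_reward_value(self, linear_u):
        assert sc.q_leisure(0.0, rho=3.7, u=linear_u, V_pre=1.25) == 1.25

    def test_leisure_constant_when_marginal_equals_rate(self):
        u = lu.linear(0.5)
        q = sc.q_leisure(np.linspace(0, 20, 50), rho=0.5, u=u, V_pre=2.0)
        np.testing.assert_allclose(q, 2.0, atol=1e-12)

    def test_leisure_utility_minus_foregone_reward(self):
        assert sc.q_leisure(4.0, rho=0.5, u=lu.linear(1.0)) == pytest.approx(2.0)

    def test_leisure_domain_error(self, linear_u):
        with pytest.raises(ValueError):
            sc.q_leisure(11.0, rho=1.0, u=linear_u, tau_max=10.0)

    @pytest.mark.parametrize(
        "R_I, rho, P, expected",
        [(10.0, 1.0, 5.0, 5.0), (10.0, 2.0, 5.0, 0.0), (0.0, 1.5, 4.0, -6.0)],
    )
    def test_work_value(self, R_I, rho, P, expected):
        task = sc.TaskSpec(R_I=R_I, P=P)
        assert sc.q_work(rho, task) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Softmax policy
# ---------------------------------------------------------------------------


class TestSoftmaxPolicy:
    def test_zero_inverse_temperature_gives_uniform(self):
        grid, d = sc.softmax_policy(lambda t: -3.0 * t + 1.0, beta=0.0,
                                    tau_max=8.0)
        np.testing.assert_allclose(d, 1.0 / 8.0)

    def test_constant_q_gives_uniform(self):
        grid, d = sc.softmax_policy(lambda t: np.full_like(t, 4.2), beta=2.0,
                                    tau_max=10.0)
        np.testing.assert_allclose(d, 0.1, atol=1e-14)

    def test_linear_q_gives_truncated_exponential_mean(self):
        """q = -tau at beta 1 on [0, 10]: mean is 1 - 10/(e^10 - 1),
        checked against a dense-quadrature oracle."""
        analytic = 1.0 - 10.0 / math.expm1(10.0)
        grid, d = sc.softmax_policy(lambda t: -t, beta=1.0, tau_max=10.0,
                                    grid_n=100001)
        oracle = simpson(d * grid, x=grid)
        assert oracle == pytest.approx(analytic, abs=1e-9)
        g2, d2 = sc.softmax_policy(lambda t: -t, beta=1.0, tau_max=10.0)
        assert np.trapezoid(d2 * g2, g2) == pytest.approx(analytic, abs=1e-5)

    @given(shift=st.floats(-1e3, 1e3), seed=st.integers(0, 100))
    def test_shift_invariance(self, shift, seed):
        """Adding a constant to all Q-values leaves the policy unchanged:
        anchoring V_post = 0 is harmless."""
        rng = np.random.default_rng(seed)
        q = rng.normal(size=501).cumsum() * 0.05
        _, d1 = sc.softmax_policy(q, beta=1.3, tau_max=10.0, grid_n=501)
        _, d2 = sc.softmax_policy(q + shift, beta=1.3, tau_max=10.0,
                                  grid_n=501)
        assert np.max(np.abs(d1 - d2)) < 1e-12

    def test_normalization(self):
        grid, d = sc.softmax_policy(lambda t: np.sin(t), beta=2.0,
                                    tau_max=30.0)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-10)
        assert np.all(d >= 0)

    def test_nonfinite_q_rejected(self):
        with pytest.raises(FloatingPointError):
            sc.softmax_policy(lambda t: np.where(t > 1, np.nan, -t),
                              beta=1.0, tau_max=5.0)


# ---------------------------------------------------------------------------
# Reward rate
# ---------------------------------------------------------------------------


class TestRewardRate:
    def test_point_policy(self, default_task):
        u = lu.linear(0.0)
        assert sc.reward_rate(None, None, u, default_task, atom=5.0) == 1.0
        assert sc.reward_rate(None, None, u, default_task, atom=0.0) == 2.0

    def test_uniform_policy_linear_utility(self):
        """Uniform on [0,10] with C_L=1, R_I=10, P=5:
        (10 + 5) / (5 + 5) = 1.5."""
        task = sc.TaskSpec(R_I=10.0, P=5.0, tau_max=10.0)
        grid = np.linspace(0, 10, 2001)
        d = np.full_like(grid, 0.1)
        assert sc.reward_rate(d, grid, lu.linear(1.0), task) == pytest.approx(
            1.5, abs=1e-12
        )

    def test_unnormalized_density_rejected(self, default_task, linear_u):
        grid = np.linspace(0, 10, 101)
        with pytest.raises(ValueError):
            sc.reward_rate(np.ones_like(grid), grid, linear_u, default_task)


# ---------------------------------------------------------------------------
# Fixed-point solver
# ---------------------------------------------------------------------------


class TestSolve:
    def test_against_closed_form_root(self):
        """Linear C_L=0 reduces to a scalar fixed point on the analytic
        truncated-exponential mean; an independent bracketing root-finder
        on that closed form agrees with the solver to 1e-8."""
        task = sc.TaskSpec(R_I=10.0, P=5.0, tau_max=10.0)
        u = lu.linear(0.0)
        pol = sc.solve(task, u, sc.PolicySettings(beta=1.0, grid_n=200001))
        rho_oracle = brentq(
            lambda r: task.R_I / (task.P + trunc_exp_mean(r, 10.0)) - r,
            1e-9, 10.0, xtol=1e-14,
        )
        assert abs(pol.rho - rho_oracle) < 1e-8

    def test_log_utility_policy_is_truncated_gamma(self, solved_log, log_u):
        """Solver density equals the closed-form truncated gamma with
        shape beta*C_L + 1 and rate beta*rho, to sup-norm 1e-6."""
        d = sc.closed_form_distribution(log_u, 1.0, solved_log.rho,
                                        solved_log.task.tau_max)
        assert d.shape == pytest.approx(6.0)
        assert d.rate == pytest.approx(solved_log.rho)
        assert np.max(np.abs(d.pdf(solved_log.grid) - solved_log.density)) < 1e-6

    def test_fixed_point_residual(self, solved_linear, linear_u, default_task):
        rate = sc.reward_rate(solved_linear.density, solved_linear.grid,
                              linear_u, default_task)
        assert abs(rate - solved_linear.rho) < 1e-9

    def test_iterate_and_root_solvers_agree(self, default_task, log1p_u):
        a = sc.solve(default_task, log1p_u, sc.PolicySettings(solver="iterate"))
        b = sc.solve(default_task, log1p_u, sc.PolicySettings(solver="root"))
        assert a.converged and b.converged
        assert abs(a.rho - b.rho) < 1e-8

    def test_all_work_corner_at_infinite_beta(self):
        """Linear utility with payoff above the marginal utility of
        leisure: deterministic choice works all the time."""
        task = sc.TaskSpec(R_I=10.0, P=5.0)
        pol = sc.solve(task, lu.linear(0.2),
                       sc.PolicySettings(beta=math.inf))
        assert pol.atom == 0.0
        assert pol.rho == pytest.approx(2.0)
        assert pol.mean_leisure == 0.0

    def test_variational_optimality(self, solved_linear, linear_u,
                                    default_task):
        """The solved policy maximizes E[Q] + H/beta among perturbed
        normalized densities."""
        grid, d = solved_linear.grid, solved_linear.density
        q = sc.q_leisure(grid, solved_linear.rho, linear_u,
                         solved_linear.V_pre)

        def objective(p):
            with np.errstate(divide="ignore"):
                plogp = np.where(p > 0, p * np.log(p), 0.0)
            return np.trapezoid(p * q, grid) - np.trapezoid(plogp, grid)

        j_star = objective(d)
        rng = np.random.default_rng(7)
        for _ in range(100):
            pert = np.abs(d + rng.normal(scale=0.02, size=d.size))
            pert /= np.trapezoid(pert, grid)
            assert objective(pert) <= j_star + 1e-12

    def test_mean_leisure_decreases_with_payoff(self, linear_u, log1p_u):
        for u in (linear_u, log1p_u):
            means = [
                sc.solve(sc.TaskSpec(R_I=R, P=5.0, tau_max=50.0), u).mean_leisure
                for R in np.linspace(2.0, 40.0, 8)
            ]
            assert np.all(np.diff(means) < 0)

    def test_rho_decreases_with_price(self, log1p_u):
        rhos = [
            sc.solve(sc.TaskSpec(R_I=10.0, P=P), log1p_u).rho
            for P in np.linspace(2.0, 40.0, 8)
        ]
        assert np.all(np.diff(rhos) < 0)

    def test_beta_limits(self, default_task, log1p_u):
        """beta -> 0 recovers the uniform policy; large beta concentrates
        mass at the deterministic optimum."""
        pol0 = sc.solve(default_task, log1p_u, sc.PolicySettings(beta=0.0))
        np.testing.assert_allclose(pol0.density, 1.0 / default_task.tau_max)
        det = sc.deterministic_policy(default_task, log1p_u)
        pol_big = sc.solve(default_task, log1p_u,
                           sc.PolicySettings(beta=200.0))
        assert abs(pol_big.mean_leisure - det.atom) < 0.05

    def test_grid_refinement_converges(self, default_task, linear_u):
        rhos = [
            sc.solve(default_task, linear_u,
                     sc.PolicySettings(grid_n=n)).rho
            for n in (1001, 2001, 4001)
        ]
        assert abs(rhos[2] - rhos[1]) < abs(rhos[1] - rhos[0])

    def test_entropy_consistent_rate_differs_at_small_beta(self, default_task,
                                                           linear_u):
        base = sc.solve(default_task, linear_u,
                        sc.PolicySettings(beta=0.5)).rho
        soft = sc.solve(
            default_task, linear_u,
            sc.PolicySettings(beta=0.5, include_entropy_in_rate=True),
        ).rho
        assert soft != pytest.approx(base, abs=1e-6)

    def test_leisure_dominant_regime(self):
        """When the marginal utility of leisure exceeds the payoff, the
        deterministic policy sits at the top of the duration range."""
        task = sc.TaskSpec(R_I=10.0, P=5.0)
        pol = sc.deterministic_policy(task, lu.linear(5.0))
        assert pol.atom == task.tau_max


class TestDeterministicPolicy:
    def test_interior_optimum_concave_utility(self, default_task, log1p_u):
        """Grid argmax oracle at 1e5 points confirms the first-order
        condition marginal(U_L)(tau*) = rho at the interior optimum."""
        pol = sc.deterministic_policy(default_task, log1p_u)
        tau = np.linspace(0.0, default_task.tau_max, 100001)
        rates = (default_task.R_I + log1p_u.evaluate(tau)) / (
            default_task.P + tau
        )
        tau_oracle = tau[np.argmax(rates)]
        assert abs(pol.atom - tau_oracle) < 2 * default_task.tau_max / 1e5
        assert log1p_u.marginal(pol.atom) == pytest.approx(pol.rho, rel=1e-6)
        assert 0.0 < pol.atom < default_task.tau_max


class TestClosedFormDistribution:
    def test_linear_parameters(self):
        d = sc.closed_form_distribution(lu.linear(0.5), beta=1.0, rho=2.0,
                                        tau_max=50.0)
        assert d.family is sc.DistributionFamily.TRUNCATED_EXPONENTIAL
        assert d.rate == pytest.approx(1.5)

    def test_log_parameters(self):
        d = sc.closed_form_distribution(lu.log(3.0), beta=2.0, rho=1.0,
                                        tau_max=50.0)
        assert d.shape == pytest.approx(7.0)
        assert d.rate == pytest.approx(2.0)

    def test_no_closed_form_for_log1p(self, log1p_u):
        with pytest.raises(sc.ClosedFormUnavailable):
            sc.closed_form_distribution(log1p_u, beta=1.0, rho=1.0,
                                        tau_max=10.0)

    def test_moments_match_dense_quadrature(self, solved_log, log_u):
        d = sc.closed_form_distribution(log_u, 1.0, solved_log.rho,
                                        solved_log.task.tau_max)
        grid = np.linspace(0.0, solved_log.task.tau_max, 100001)
        pdf = d.pdf(grid)
        assert d.mean() == pytest.approx(simpson(pdf * grid, x=grid),
                                         abs=1e-6)
        assert d.mode() == pytest.approx(grid[np.argmax(pdf)], abs=1e-3)

    def test_negative_rate_density_increases(self):
        d = sc.LeisureDistribution("truncated_exponential", truncation=10.0,
                                   rate=-0.5)
        grid = np.linspace(0, 10, 101)
        assert np.all(np.diff(d.pdf(grid)) > 0)
        assert d.mode() == 10.0
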