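"""Tests of the two integration schemes against independent oracles."""

import math

import numpy as np
import pytest

from delaydcm import (
    ERPParameters,
    IntegrationError,
    NetworkSpec,
    SolverOptions,
    delay_compensated_field,
    rk_integrate,
    rk_solve,
    rk_step,
    ta_integrate,
)
from delaydcm.integrators import _phi1_times_tau
from delaydcm.model import ERPField, jacobian_nodelay, state_delay_matrix


def two_region(delay=8.0, backward=0.0):
    AF = np.zeros((2, 2))
    AF[1, 0] = 8.0
    AB = np.zeros((2, 2))
    AB[0, 1] = backward
    D = np.zeros((2, 2))
    D[1, 0] = delay
    if backward:
        D[0, 1] = delay
    return NetworkSpec(2, A_forward=AF, A_backward=AB, C_input=[1, 0],
                       D_extrinsic=D)


class TestPhi1:
    def test_scalar_linear_step_is_exact(self):
        # x(t+tau) = x + U a x with U = (e^(a tau) - 1)/a reproduces e^(a tau)
        a, tau = -0.37, 0.8
        U = _phi1_times_tau(np.array([[a]]), tau)[0, 0]
        assert 1.0 + U * a == pytest.approx(math.exp(a * tau), rel=1e-12)

    def test_zero_jacobian_reduces_to_euler(self):
        U = _phi1_times_tau(np.zeros((4, 4)), 0.5)
        assert np.allclose(U, 0.5 * np.eye(4), atol=1e-14)

    def test_handles_singular_jacobian(self):
        # structurally singular J (zero row) must still give a finite U
        J = np.array([[0.0, 1.0], [0.0, -2.0]])
        U = _phi1_times_tau(J, 1.0)
        assert np.all(np.isfinite(U))


class TestDelayCompensation:
    def test_zero_delays_equal_plain_field(self):
        net = two_region(delay=0.0)
        params = ERPParameters(d_intrinsic=1e-12)
        x = np.random.default_rng(0).normal(0, 1, 18)
        fld = ERPField(net, params, "baseline")
        psi = delay_compensated_field(30.0, x, net, params)
        assert np.allclose(psi, fld.nodelay(30.0, x), rtol=1e-9, atol=1e-12)

    def test_self_consistency_equation(self):
        # psi solves (I + D o J) psi = f(x, no delays) by definition
        net = two_region(delay=8.0, backward=2.0)
        params = ERPParameters()
        x = np.random.default_rng(1).normal(0, 1, 18)
        psi = delay_compensated_field(30.0, x, net, params)
        J = jacobian_nodelay(x, net, params)
        D = state_delay_matrix(net, params)
        fld = ERPField(net, params, "baseline")
        lhs = (np.eye(18) + D * J) @ psi
        assert np.allclose(lhs, fld.nodelay(30.0, x), rtol=1e-9)

    def test_rows_without_delayed_input_unchanged(self):
        # voltage rows and the pyramidal-depolarization row read only
        # same-population states, so compensation leaves them untouched
        net = two_region(delay=8.0, backward=2.0)
        params = ERPParameters()
        x = np.random.default_rng(2).normal(0, 1, 18)
        psi = delay_compensated_field(30.0, x, net, params)
        phi = ERPField(net, params, "baseline").nodelay(30.0, x)
        for r in (0, 1, 2, 6, 8, 9, 10, 11, 15, 17):
            assert psi[r] == pytest.approx(phi[r], rel=1e-12, abs=1e-12)


class TestRKStep:
    def test_constant_and_zero_fields_exact(self):
        hist = lambda tq: np.zeros(1)
        x = np.array([2.0])
        xn, err, _ = rk_step(0.0, x, 0.3, hist, lambda t, x, lag: 0.0 * x)
        assert xn == pytest.approx(2.0) and np.allclose(err, 0.0)
        xn, err, _ = rk_step(0.0, x, 0.3, hist,
                             lambda t, x, lag: np.ones_like(x))
        assert xn == pytest.approx(2.3) and np.allclose(err, 0.0, atol=1e-15)

    def test_local_error_scales_as_h4(self):
        # Richardson step-halving oracle on x' = -x
        lam = -1.0

        def field(t, x, lag):
            return lam * x

        def true_err(h):
            hist = lambda tq: np.array([1.0])
            xn, _, _ = rk_step(0.0, np.array([1.0]), h, hist, field)
            return abs(xn[0] - math.exp(lam * h))

        r = true_err(0.1) / true_err(0.05)
        assert r == pytest.approx(16.0, rel=0.15)


class TestRKSolve:
    def test_scalar_linear_dde_matches_method_of_steps(self):
        # x'(t) = -x(t-1), x = 1 for t <= 0:
        # 1 - t on [0,1]; 1 - t + (t-1)^2/2 on [1,2]
        opts = SolverOptions()
        tg = np.linspace(0.0, 2.0, 81)
        traj = rk_solve(lambda t, x, lag: -lag(1.0), 1, 1.0, opts, tg,
                        x0=np.array([1.0]))
        exact = np.where(tg <= 1.0, 1.0 - tg,
                         1.0 - tg + 0.5 * (tg - 1.0) ** 2)
        assert np.abs(traj.sampled_states[:, 0] - exact).max() \
            < 10.0 * opts.rel_tol

    def test_zero_delay_matches_scipy_reference(self):
        from scipy.integrate import solve_ivp

        net = two_region(delay=8.0, backward=2.0)
        params = ERPParameters()
        fld = ERPField(net, params, "baseline")
        ode = lambda t, x: fld(t, x, lambda d: x)
        tg = np.arange(0.0, 201.0, 1.0)
        opts = SolverOptions(rel_tol=1e-3, abs_tol=1e-6)
        traj = rk_solve(lambda t, x, lag: ode(t, x), 18, None, opts, tg)
        ref = solve_ivp(ode, (0.0, 200.0), np.zeros(18), t_eval=tg,
                        rtol=1e-9, atol=1e-12, method="RK45")
        scale = np.abs(ref.y).max()
        assert np.abs(traj.sampled_states - ref.y.T).max() \
            < 10.0 * (opts.rel_tol * scale + opts.abs_tol)

    def test_interpolant_reproduces_mesh_states(self):
        net = two_region(16.0)
        traj = rk_integrate(net, ERPParameters(), "baseline",
                            SolverOptions(), np.arange(0.0, 201.0, 1.0))
        vals = traj.evaluate(traj.mesh_times)
        assert np.allclose(vals, traj.states, rtol=1e-12, atol=1e-12)

    def test_tolerance_convergence(self):
        net = two_region(16.0, backward=2.0)
        tg = np.arange(0.0, 401.0, 1.0)
        y3 = rk_integrate(net, ERPParameters(), "baseline",
                          SolverOptions(rel_tol=1e-3), tg).sampled_states
        y5 = rk_integrate(net, ERPParameters(), "baseline",
                          SolverOptions(rel_tol=1e-5), tg).sampled_states
        assert np.abs(y3 - y5).max() < 10.0 * 1e-3

    def test_finite_time_blowup_raises(self):
        # x' = x^2, x(0) = 1 escapes to infinity at t = 1
        blowup = lambda t, x, lag: x ** 2
        with pytest.raises(IntegrationError):
            rk_solve(blowup, 1, None, SolverOptions(max_steps=50_000),
                     np.linspace(0.0, 2.0, 21), x0=np.array([1.0]))


class TestTAIntegrate:
    def test_rest_stays_at_rest(self):
        net = two_region(8.0)
        traj = ta_integrate(net, ERPParameters(input_amplitude=0.0),
                            "baseline", SolverOptions(scheme="ta"),
                            np.arange(0.0, 101.0, 1.0))
        assert np.allclose(traj.sampled_states, 0.0, atol=1e-12)

    def test_divergence_reports_step(self, monkeypatch):
        # a non-finite state must abort with the offending step index
        from delaydcm import model as model_mod

        monkeypatch.setattr(
            model_mod.ERPField, "nodelay",
            lambda self, t, x: np.full(self.nu, np.nan))
        net = two_region(8.0)
        with pytest.raises(IntegrationError, match="step 1"):
            ta_integrate(net, ERPParameters(), "baseline",
                         SolverOptions(scheme="ta"),
                         np.arange(0.0, 101.0, 1.0))

    def test_nonuniform_grid_rejected(self):
        net = two_region(8.0)
        with pytest.raises(ValueError):
            ta_integrate(net, ERPParameters(), "baseline",
                         SolverOptions(scheme="ta"),
                         np.array([0.0, 1.0, 3.0]))


class TestSchemeComparison:
    def test_ta_rk_discrepancy_grows_with_delay(self, sweep_trajectories):
        sup = []
        for d in (4.0, 8.0, 16.0, 32.0):
            diff = np.abs(sweep_trajectories[("ta", d)]
                          - sweep_trajectories[("rk", d)]).max()
            sup.append(diff)
        assert all(b >= a * (1 - 1e-9) for a, b in zip(sup, sup[1:]))

    def test_rk_shifts_region2_by_delay_increment(self, sweep_trajectories):
        grid = np.arange(0.0, 401.0, 1.0)
        lat = {d: grid[np.argmax(sweep_trajectories[("rk", d)][1])]
               for d in (4.0, 8.0, 16.0, 32.0)}
        for d in (8.0, 16.0, 32.0):
            assert lat[d] - lat[4.0] == pytest.approx(d - 4.0, abs=1.0)

    def test_ta_attenuates_latency_shift(self, sweep_trajectories):
        grid = np.arange(0.0, 401.0, 1.0)
        lat = {d: grid[np.argmax(sweep_trajectories[("ta", d)][1])]
               for d in (4.0, 32.0)}
        assert lat[32.0] - lat[4.0] < 28.0 - 1.0
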