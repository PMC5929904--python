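"""Unit and property tests of the neural-mass model building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delaydcm import ERPParameters, NetworkSpec, evolution, input_function, \
    jacobian_nodelay, sigmoid, state_delay_matrix
from delaydcm.model import ERPField, N_STATES, POPULATION, V_PYR


def single_region():
    return NetworkSpec(1, C_input=[1.0])


def two_region_forward(delay=8.0):
    AF = np.zeros((2, 2))
    AF[1, 0] = 8.0
    D = np.zeros((2, 2))
    D[1, 0] = delay
    return NetworkSpec(2, A_forward=AF, C_input=[1.0, 0.0], D_extrinsic=D)


class TestSigmoid:
    def test_zero_at_rest(self):
        assert sigmoid(0.0) == pytest.approx(0.0, abs=1e-15)

    # strictness holds where the logistic is resolvable in double precision
    @given(st.floats(-8, 8), st.floats(-8, 8))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_strictly_increasing(self, v1, v2):
        if abs(v1 - v2) < 1e-9:  # below float resolution of the logistic
            return
        lo, hi = sorted((v1, v2))
        assert sigmoid(lo) < sigmoid(hi)

    def test_bounded(self):
        v = np.linspace(-1e3, 1e3, 101)
        assert np.all(np.abs(sigmoid(v)) <= 1.0)

    def test_closed_form_value(self):
        expected = 1.0 / (1.0 + math.exp(-2.0 * 9.0)) \
            - 1.0 / (1.0 + math.exp(2.0))
        assert sigmoid(10.0, rho1=2.0, rho2=1.0) == pytest.approx(expected,
                                                                  rel=1e-12)


class TestInput:
    def test_peak_at_onset(self):
        t = np.linspace(0, 400, 4001)
        u = input_function(t, onset=64.0, width=8.0)
        assert t[np.argmax(u)] == pytest.approx(64.0, abs=0.1)

    def test_gaussian_shape(self):
        u0 = input_function(64.0, 64.0, 8.0)
        assert input_function(72.0, 64.0, 8.0) / u0 == pytest.approx(
            math.exp(-0.5), rel=1e-12)
        assert input_function(56.0, 64.0, 8.0) / u0 == pytest.approx(
            math.exp(-0.5), rel=1e-12)

    def test_quadrature_mass(self):
        # trapezoid oracle: integral of a Gaussian bump
        t = np.linspace(-400, 400, 80001)
        mass = np.trapezoid(input_function(t, 64.0, 8.0, 2.0), t)
        assert mass == pytest.approx(2.0 * 8.0 * math.sqrt(2 * math.pi),
                                     rel=1e-6)


class TestEvolution:
    def test_rest_is_fixed_point(self):
        net = two_region_forward()
        params = ERPParameters(input_amplitude=0.0)
        x = np.zeros(net.n_states)
        dx = evolution(100.0, x, lambda i, d: 0.0, net, params)
        assert np.allclose(dx, 0.0, atol=1e-14)

    def test_dimension_mismatch_raises(self):
        net = two_region_forward()
        with pytest.raises(ValueError):
            evolution(0.0, np.zeros(9), lambda i, d: 0.0, net,
                      ERPParameters())

    def test_matches_vectorized_field(self):
        # the integrator's vectorized field is the same function
        net = two_region_forward()
        params = ERPParameters()
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2, net.n_states)
        fld = ERPField(net, params, "baseline")
        a = fld(50.0, x, lambda d: x * math.cos(d))
        b = evolution(50.0, x, lambda i, d: x[i] * math.cos(d), net, params)
        assert np.allclose(a, b, rtol=1e-12, atol=1e-14)

    def test_synaptic_kernel_peak(self):
        # a single uncoupled excitatory synapse driven by a near-impulse
        # peaks one time constant after the input, like H (t/tau) e^(-t/tau)
        from delaydcm import SolverOptions, rk_integrate

        params = ERPParameters(gamma1=1e-9, gamma2=1e-9, gamma3=1e-9,
                               gamma4=1e-9, input_onset=5.0,
                               input_width=0.25)
        net = single_region()
        grid = np.arange(0.0, 60.0, 0.25)
        traj = rk_integrate(net, params, "baseline",
                            SolverOptions(rel_tol=1e-5), grid)
        v1 = traj.sampled_states[:, 0]
        t_peak = grid[np.argmax(v1)]
        assert t_peak == pytest.approx(5.0 + params.tau_e, abs=1.5)

    def test_modulated_equals_baseline_when_factors_one(self):
        net = sim1_like()
        params = ERPParameters(modulation_factors={
            "forward": np.ones((2, 2)), "backward": np.ones((2, 2))})
        x = np.random.default_rng(3).normal(0, 1, net.n_states)
        fb = ERPField(net, params, "baseline")
        fm = ERPField(net, params, "modulated")
        lag = lambda d: x * 0.9
        assert np.array_equal(fb(10.0, x, lag), fm(10.0, x, lag))

    def test_modulation_scales_masked_connection(self):
        net = sim1_like()
        params = ERPParameters(modulation_factors={
            "forward": np.full((2, 2), 0.5),
            "backward": np.full((2, 2), 0.8)})
        from delaydcm.model import effective_gains

        GF_b, GB_b, _, _ = effective_gains(net, params, "baseline")
        GF_m, GB_m, _, _ = effective_gains(net, params, "modulated")
        assert GF_m[1, 0] == pytest.approx(0.5 * GF_b[1, 0])
        assert GB_m[0, 1] == pytest.approx(0.8 * GB_b[0, 1])


def sim1_like():
    AF = np.zeros((2, 2))
    AF[1, 0] = 8.0
    AB = np.zeros((2, 2))
    AB[0, 1] = 2.0
    D = np.full((2, 2), 16.0)
    np.fill_diagonal(D, 0.0)
    mf = AF > 0
    mb = AB > 0
    return NetworkSpec(2, A_forward=AF, A_backward=AB, C_input=[1, 0],
                       D_extrinsic=D, mod_mask_forward=mf,
                       mod_mask_backward=mb)


class TestJacobian:
    def test_matches_finite_differences(self):
        net = sim1_like()
        params = ERPParameters()
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 2.0, net.n_states)
        J = jacobian_nodelay(x, net, params)
        fld = ERPField(net, params, "baseline")
        eps = 1e-6
        JF = np.empty_like(J)
        for j in range(net.n_states):
            e = np.zeros(net.n_states)
            e[j] = eps
            JF[:, j] = (fld.nodelay(0, x + e) - fld.nodelay(0, x - e)) \
                / (2 * eps)
        assert np.max(np.abs(J - JF)) < 1e-6 * (1.0 + np.abs(J).max())

    def test_uncoupled_eigenvalue_pattern(self):
        # with intrinsic couplings off, each second-order synapse is a
        # companion block with a double eigenvalue -1/tau
        params = ERPParameters(gamma1=0.0, gamma2=0.0, gamma3=0.0,
                               gamma4=0.0)
        J = jacobian_nodelay(np.zeros(9), single_region(), params)
        ev = np.sort(np.linalg.eigvals(J).real)
        expected = np.sort([-1 / 8.0] * 6 + [-1 / 16.0] * 2 + [0.0])
        assert np.allclose(ev, expected, atol=1e-10)


class TestDelayMatrix:
    def test_structure(self):
        net = sim1_like()
        params = ERPParameters()
        D = state_delay_matrix(net, params)
        # same population, same region: zero delay
        assert D[0, 3] == 0.0  # stellate voltage reads stellate current
        assert D[8, 4] == 0.0  # pyramidal depolarization reads own currents
        # distinct populations, same region: intrinsic delay
        assert D[3, 8] == params.d_intrinsic
        # distinct regions: extrinsic delay
        assert D[9, 8] == 16.0
        blocks = D[:9, :9]
        same_pop = POPULATION[:, None] == POPULATION[None, :]
        assert np.all(blocks[same_pop] == 0.0)
        assert np.all(blocks[~same_pop] == params.d_intrinsic)


class TestCausality:
    def test_zero_history_zero_input_stays_at_rest(self):
        from delaydcm import SolverOptions, rk_integrate

        rng = np.random.default_rng(5)
        AF = rng.uniform(0, 2, (3, 3))
        np.fill_diagonal(AF, 0.0)
        D = rng.uniform(4, 32, (3, 3))
        np.fill_diagonal(D, 0.0)
        net = NetworkSpec(3, A_forward=AF, D_extrinsic=D)  # no input
        traj = rk_integrate(net, ERPParameters(input_amplitude=0.0),
                            "baseline", SolverOptions(),
                            np.arange(0.0, 401.0, 1.0))
        assert np.allclose(traj.sampled_states, 0.0, atol=1e-12)

    def test_region2_silent_before_delay_arrival(self):
        from delaydcm import SolverOptions, rk_integrate

        grid = np.arange(0.0, 201.0, 1.0)
        params = ERPParameters(input_onset=40.0)
        lead_times = {}
        for delay in (8.0, 32.0):
            net = two_region_forward(delay)
            traj = rk_integrate(net, params, "baseline",
                                SolverOptions(rel_tol=1e-4), grid)
            r2 = np.abs(traj.sampled_states[:, 9:]).max(axis=1)
            lead_times[delay] = grid[np.argmax(r2 > 1e-8)]
        # increasing the conduction delay postpones region-2 onset by the
        # same amount (delay locality)
        assert lead_times[32.0] - lead_times[8.0] == pytest.approx(24.0,
                                                                   abs=1.0)
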