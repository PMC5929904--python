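"""Three-subpopulation ERP neural mass model on arbitrary region networks.

Each region contains a spiny-stellate (granular) population, a pyramidal
population and an inhibitory interneuron population.  Synaptic transmission is
a second-order linear operator (gain ``H``, time constant ``tau``) driven by
sigmoid-transformed presynaptic depolarizations; axonal transmission introduces
conduction delays, making the full system a set of delay differential
equations

    dx/dt = f(t, u(t), x(t - d_kl))

where ``d_kl`` is zero within a population, the intrinsic delay between
distinct populations of one region, and the extrinsic delay between regions.

Connectivity follows the standard ERP-DCM rules: forward connections target
the stellate population, backward connections target pyramidal and inhibitory
populations, lateral connections target all of them.  The observed quantity is
the pyramidal depolarization of each region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "NetworkSpec",
    "ERPParameters",
    "N_STATES",
    "state_index",
    "sigmoid",
    "sigmoid_derivative",
    "input_function",
    "evolution",
    "jacobian_nodelay",
    "state_delay_matrix",
    "ERPField",
]

# Per-region state layout.
N_STATES = 9
V_STELLATE = 0
V_PYR_EXC = 1
V_PYR_INH = 2
I_STELLATE = 3
I_PYR_EXC = 4
I_PYR_INH = 5
V_INHIB = 6
I_INHIB = 7
V_PYR = 8

#: population membership of each per-region state (0 stellate, 1 pyramidal,
#: 2 inhibitory interneurons); used to assign intrinsic conduction delays.
POPULATION = np.array([0, 1, 1, 0, 1, 1, 2, 2, 1])

#: synaptic drive terms carry a ms<->s conversion: the gains H_e/H_i and
#: coupling constants gamma are calibrated for firing rates per second,
#: while the state equations advance time in ms.
DRIVE_SCALE = 1e-3

BASELINE = "baseline"
MODULATED = "modulated"


def state_index(region: int, state: int) -> int:
    """Global index of per-region state ``state`` of ``region`` (0-based)."""
    return N_STATES * region + state


def _as_matrix(a, n, name):
    a = np.zeros((n, n)) if a is None else np.asarray(a, dtype=float)
    if a.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {a.shape}")
    return a


@dataclass
class NetworkSpec:
    """Regions, connection strengths, conduction delays and modulation masks.

    Connection matrices are dimensionless strengths; entry ``[k, l]`` is the
    connection from region ``l`` to region ``k``.  Natural coupling gains are
    obtained by multiplying with the per-type base gains in
    :class:`ERPParameters`.  ``D_extrinsic`` holds extrinsic conduction delays
    in ms.  Boolean masks mark which connections (or regions, for intrinsic
    gain) carry a condition-specific modulation.
    """

    n_regions: int
    A_forward: Optional[np.ndarray] = None
    A_backward: Optional[np.ndarray] = None
    A_lateral: Optional[np.ndarray] = None
    C_input: Optional[np.ndarray] = None
    D_extrinsic: Optional[np.ndarray] = None
    mod_mask_forward: Optional[np.ndarray] = None
    mod_mask_backward: Optional[np.ndarray] = None
    mod_mask_intrinsic: Optional[np.ndarray] = None

    def __post_init__(self):
        n = self.n_regions
        if n < 1:
            raise ValueError("n_regions must be a positive integer")
        self.A_forward = _as_matrix(self.A_forward, n, "A_forward")
        self.A_backward = _as_matrix(self.A_backward, n, "A_backward")
        self.A_lateral = _as_matrix(self.A_lateral, n, "A_lateral")
        self.D_extrinsic = _as_matrix(self.D_extrinsic, n, "D_extrinsic")
        self.C_input = (
            np.zeros(n) if self.C_input is None
            else np.asarray(self.C_input, dtype=float)
        )
        if self.C_input.shape != (n,):
            raise ValueError("C_input must have length n_regions")
        for name in ("A_forward", "A_backward", "A_lateral", "D_extrinsic"):
            m = getattr(self, name)
            if np.any(np.diag(m) != 0):
                raise ValueError(f"diagonal of {name} must be zero")
            if np.any(m < 0):
                raise ValueError(f"{name} entries must be nonnegative")
        if np.any(self.C_input < 0):
            raise ValueError("C_input entries must be nonnegative")
        for name, ref in (
            ("mod_mask_forward", self.A_forward),
            ("mod_mask_backward", self.A_backward),
        ):
            m = getattr(self, name)
            m = (np.zeros((n, n), bool) if m is None
                 else np.asarray(m, dtype=bool))
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if np.any(m & (ref == 0)):
                raise ValueError(f"{name} marks absent connections")
            setattr(self, name, m)
        mi = self.mod_mask_intrinsic
        mi = np.zeros(n, bool) if mi is None else np.asarray(mi, dtype=bool)
        if mi.shape != (n,):
            raise ValueError("mod_mask_intrinsic must have length n_regions")
        self.mod_mask_intrinsic = mi

    @property
    def n_states(self) -> int:
        """Global state dimension (9 states per region)."""
        return N_STATES * self.n_regions


@dataclass
class ERPParameters:
    """Synaptic, sigmoid, delay and input constants of the ERP model.

    Times are in ms, gains in mV.  ``tau_e``/``tau_i`` and the intrinsic
    coupling constants ``gamma1..4`` follow the Jansen–Rit lineage of the
    ERP model; extrinsic connections are scaled by per-type base gains
    (``g_forward``/``g_backward``/``g_lateral``/``g_input``) times the
    dimensionless strengths in :class:`NetworkSpec`.

    ``modulation_factors`` holds the multiplicative gains applied to masked
    connections in the modulated condition: a dict with optional keys
    ``"forward"``, ``"backward"`` (n x n arrays) and ``"intrinsic"``
    (length-n array, applied to the region's excitatory gain H_e).
    """

    tau_e: float = 8.0
    tau_i: float = 16.0
    H_e: float = 3.25
    H_i: float = 22.0
    gamma1: float = 128.0
    gamma2: float = 0.8 * 128.0
    gamma3: float = 0.25 * 128.0
    gamma4: float = 0.25 * 128.0
    rho1: float = 2.0
    rho2: float = 1.0
    d_intrinsic: float = 2.0
    input_onset: float = 64.0
    input_width: float = 8.0
    input_amplitude: float = 1.0
    g_forward: float = 32.0
    g_backward: float = 16.0
    g_lateral: float = 4.0
    g_input: float = 32.0
    modulation_factors: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "d_intrinsic", "input_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rho1 <= 0:
            raise ValueError("rho1 must be > 0")
        for key, fac in self.modulation_factors.items():
            if key not in ("forward", "backward", "intrinsic"):
                raise ValueError(f"unknown modulation key {key!r}")
            if np.any(np.asarray(fac, dtype=float) <= 0):
                raise ValueError("modulation factors must be > 0")


def sigmoid(v, rho1: float = 2.0, rho2: float = 1.0):
    """Sigmoid voltage-to-firing transform, normalized to zero at rest.

    ``S(v) = 1/(1+exp(-rho1 (v-rho2))) - 1/(1+exp(rho1 rho2))`` so S(0)=0,
    S is strictly increasing and bounded.
    """
    from scipy.special import expit

    v = np.asarray(v, dtype=float)
    out = expit(rho1 * (v - rho2)) - expit(-rho1 * rho2)
    return out if out.ndim else float(out)


def sigmoid_derivative(v, rho1: float = 2.0, rho2: float = 1.0):
    """dS/dv of :func:`sigmoid`."""
    from scipy.special import expit

    v = np.asarray(v, dtype=float)
    s = expit(rho1 * (v - rho2))
    out = rho1 * s * (1.0 - s)
    return out if out.ndim else float(out)


def input_function(t, onset: float = 64.0, width: float = 8.0,
                   amplitude: float = 1.0):
    """Gaussian stimulus bump peaking at ``onset`` (ms) with sd ``width``."""
    t = np.asarray(t, dtype=float)
    out = amplitude * np.exp(-0.5 * ((t - onset) / width) ** 2)
    return out if out.ndim else float(out)


def effective_gains(net: NetworkSpec, params: ERPParameters, condition: str):
    """Natural coupling matrices and per-region H_e for one condition.

    Returns ``(GF, GB, GL, He_region)`` where GF/GB/GL are the forward,
    backward and lateral gain matrices (base gain x strength, with the
    condition's modulation factors applied on masked entries) and
    ``He_region`` the per-region excitatory synaptic gain.
    """
    if condition not in (BASELINE, MODULATED):
        raise ValueError(f"unknown condition {condition!r}")
    GF = params.g_forward * net.A_forward
    GB = params.g_backward * net.A_backward
    GL = params.g_lateral * net.A_lateral
    He = np.full(net.n_regions, params.H_e)
    if condition == MODULATED:
        mf = params.modulation_factors
        if "forward" in mf:
            fac = np.asarray(mf["forward"], dtype=float)
            GF = GF * np.where(net.mod_mask_forward, fac, 1.0)
        if "backward" in mf:
            fac = np.asarray(mf["backward"], dtype=float)
            GB = GB * np.where(net.mod_mask_backward, fac, 1.0)
        if "intrinsic" in mf:
            fac = np.asarray(mf["intrinsic"], dtype=float)
            He = He * np.where(net.mod_mask_intrinsic, fac, 1.0)
    return GF, GB, GL, He


def evolution(t: float, x: np.ndarray,
              delayed_lookup: Callable[[int, float], float],
              net: NetworkSpec, params: ERPParameters,
              condition: str = BASELINE) -> np.ndarray:
    """Delayed evolution function dx/dt of the full network.

    ``delayed_lookup(state_index, delay_ms)`` must return the history value
    of that state at ``t - delay``; a zero delay means the current value.
    This is the reference (readable, scalar-lookup) implementation; the
    integrators use the vectorized :class:`ERPField` equivalent.
    """
    x = np.asarray(x, dtype=float)
    n = net.n_regions
    if x.shape != (net.n_states,):
        raise ValueError(
            f"state dimension {x.shape} does not match network "
            f"({net.n_states},)")
    GF, GB, GL, He = effective_gains(net, params, condition)
    GFL = GF + GL
    GBL = GB + GL
    p = params
    di = p.d_intrinsic
    u_t = input_function(t, p.input_onset, p.input_width, p.input_amplitude)

    def lk(region, state, delay):
        idx = state_index(region, state)
        return delayed_lookup(idx, delay) if delay > 0 else x[idx]

    dx = np.zeros_like(x)
    for k in range(n):
        X = x[N_STATES * k:N_STATES * (k + 1)]
        # intrinsic afferents (distinct populations -> intrinsic delay)
        s_pyr = sigmoid(lk(k, V_PYR, di), p.rho1, p.rho2)
        s_ste = sigmoid(lk(k, V_STELLATE, di), p.rho1, p.rho2)
        s_inh = sigmoid(lk(k, V_INHIB, di), p.rho1, p.rho2)
        # extrinsic afferents read the source pyramidal depolarization at
        # t - D_extrinsic[k, l]
        ext_f = 0.0
        ext_b = 0.0
        for l in range(n):
            if GFL[k, l] != 0.0 or GBL[k, l] != 0.0:
                s_src = sigmoid(lk(l, V_PYR, net.D_extrinsic[k, l]),
                                p.rho1, p.rho2)
                ext_f += GFL[k, l] * s_src
                ext_b += GBL[k, l] * s_src
        ke = DRIVE_SCALE * He[k] / p.tau_e
        ki = DRIVE_SCALE * p.H_i / p.tau_i
        d = dx[N_STATES * k:N_STATES * (k + 1)]
        d[V_STELLATE] = X[I_STELLATE]
        d[I_STELLATE] = (ke * (p.gamma1 * s_pyr + ext_f + net.C_input[k]
                               * p.g_input * u_t)
                         - 2.0 * X[I_STELLATE] / p.tau_e
                         - X[V_STELLATE] / p.tau_e ** 2)
        d[V_PYR_EXC] = X[I_PYR_EXC]
        d[I_PYR_EXC] = (ke * (p.gamma2 * s_ste + ext_b)
                        - 2.0 * X[I_PYR_EXC] / p.tau_e
                        - X[V_PYR_EXC] / p.tau_e ** 2)
        d[V_INHIB] = X[I_INHIB]
        d[I_INHIB] = (ke * (p.gamma3 * s_pyr + ext_b)
                      - 2.0 * X[I_INHIB] / p.tau_e
                      - X[V_INHIB] / p.tau_e ** 2)
        d[V_PYR_INH] = X[I_PYR_INH]
        d[I_PYR_INH] = (ki * p.gamma4 * s_inh
                        - 2.0 * X[I_PYR_INH] / p.tau_i
                        - X[V_PYR_INH] / p.tau_i ** 2)
        d[V_PYR] = X[I_PYR_EXC] - X[I_PYR_INH]
    return dx


class ERPField:
    """Vectorized ERP evolution function for the integrators.

    Delayed lookups go through ``xlag(delay_ms) -> full state at t - delay``;
    the field groups extrinsic connections by unique delay so one lookup per
    distinct delay value suffices.  Zero delays read the current state.
    """

    def __init__(self, net: NetworkSpec, params: ERPParameters,
                 condition: str = BASELINE):
        self.net = net
        self.params = params
        self.condition = condition
        n = net.n_regions
        self.n = n
        self.nu = net.n_states
        GF, GB, GL, He = effective_gains(net, params, condition)
        self.GFL = GF + GL
        self.GBL = GB + GL
        self.He = He
        p = params
        self.ke = DRIVE_SCALE * He / p.tau_e
        self.ki = DRIVE_SCALE * p.H_i / p.tau_i
        conn = (self.GFL != 0) | (self.GBL != 0)
        delays = np.where(conn, net.D_extrinsic, np.nan)
        uniq = np.unique(delays[conn]) if conn.any() else np.array([])
        # per unique extrinsic delay: forward+lateral / backward+lateral
        # weight matrices restricted to connections with that delay
        self.delay_groups = []
        for d in uniq:
            sel = conn & (delays == d)
            self.delay_groups.append(
                (float(d), np.where(sel, self.GFL, 0.0),
                 np.where(sel, self.GBL, 0.0)))
        self.vpyr_idx = np.arange(n) * N_STATES + V_PYR
        self.vste_idx = np.arange(n) * N_STATES + V_STELLATE
        self.vinh_idx = np.arange(n) * N_STATES + V_INHIB
        # hot-path constants
        self._intr_idx = np.concatenate(
            [self.vpyr_idx, self.vste_idx, self.vinh_idx])
        self._s_rest = 1.0 / (1.0 + np.exp(p.rho1 * p.rho2))
        self._cu = np.asarray(net.C_input, dtype=float) * p.g_input
        ds = [p.d_intrinsic] + [d for d, _, _ in self.delay_groups]
        pos = [d for d in ds if d > 0]
        #: smallest positive delay (None if the system has no delay)
        self.min_delay = min(pos) if pos else None

    def __call__(self, t: float, x: np.ndarray, xlag) -> np.ndarray:
        p = self.params
        n = self.n
        di = p.d_intrinsic
        xi = xlag(di) if di > 0 else x
        s_all = 1.0 / (1.0 + np.exp(
            -p.rho1 * (xi[self._intr_idx] - p.rho2))) - self._s_rest
        s_pyr = s_all[:n]
        s_ste = s_all[n:2 * n]
        s_inh = s_all[2 * n:]
        ext_f = np.zeros(n)
        ext_b = np.zeros(n)
        for d, WF, WB in self.delay_groups:
            xd = xlag(d) if d > 0 else x
            s_src = 1.0 / (1.0 + np.exp(
                -p.rho1 * (xd[self.vpyr_idx] - p.rho2))) - self._s_rest
            ext_f += WF @ s_src
            ext_b += WB @ s_src
        z = (t - p.input_onset) / p.input_width
        u_t = p.input_amplitude * math.exp(-0.5 * z * z)
        X = x.reshape(n, N_STATES)
        d = np.empty_like(X)
        te, ti = p.tau_e, p.tau_i
        d[:, V_STELLATE] = X[:, I_STELLATE]
        d[:, I_STELLATE] = (self.ke * (p.gamma1 * s_pyr + ext_f
                                       + self._cu * u_t)
                            - 2.0 * X[:, I_STELLATE] / te
                            - X[:, V_STELLATE] / te ** 2)
        d[:, V_PYR_EXC] = X[:, I_PYR_EXC]
        d[:, I_PYR_EXC] = (self.ke * (p.gamma2 * s_ste + ext_b)
                           - 2.0 * X[:, I_PYR_EXC] / te
                           - X[:, V_PYR_EXC] / te ** 2)
        d[:, V_INHIB] = X[:, I_INHIB]
        d[:, I_INHIB] = (self.ke * (p.gamma3 * s_pyr + ext_b)
                         - 2.0 * X[:, I_INHIB] / te
                         - X[:, V_INHIB] / te ** 2)
        d[:, V_PYR_INH] = X[:, I_PYR_INH]
        d[:, I_PYR_INH] = (self.ki * p.gamma4 * s_inh
                           - 2.0 * X[:, I_PYR_INH] / ti
                           - X[:, V_PYR_INH] / ti ** 2)
        d[:, V_PYR] = X[:, I_PYR_EXC] - X[:, I_PYR_INH]
        return d.ravel()

    def nodelay(self, t: float, x: np.ndarray) -> np.ndarray:
        """Field value with every delayed lookup replaced by the current x."""
        return self(t, x, lambda d: x)


def jacobian_nodelay(x: np.ndarray, net: NetworkSpec, params: ERPParameters,
                     condition: str = BASELINE) -> np.ndarray:
    """Jacobian of the evolution function with all delays set to zero.

    Analytic; the only nonlinearity is the sigmoid, so the Jacobian is the
    linear companion structure of the second-order synapses plus sigmoid
    slopes on the coupling terms.
    """
    x = np.asarray(x, dtype=float)
    n = net.n_regions
    nu = net.n_states
    if x.shape != (nu,):
        raise ValueError("state dimension does not match network")
    GF, GB, GL, He = effective_gains(net, params, condition)
    GFL = GF + GL
    GBL = GB + GL
    p = params
    te, ti = p.tau_e, p.tau_i
    vp = np.arange(n) * N_STATES + V_PYR
    vs = np.arange(n) * N_STATES + V_STELLATE
    vi = np.arange(n) * N_STATES + V_INHIB
    dsp = sigmoid_derivative(x[vp], p.rho1, p.rho2)   # per source region
    dss = sigmoid_derivative(x[vs], p.rho1, p.rho2)
    dsi = sigmoid_derivative(x[vi], p.rho1, p.rho2)
    J = np.zeros((nu, nu))
    ke = DRIVE_SCALE * He / te
    ki = DRIVE_SCALE * p.H_i / ti
    for k in range(n):
        b = N_STATES * k
        J[b + V_STELLATE, b + I_STELLATE] = 1.0
        J[b + V_PYR_EXC, b + I_PYR_EXC] = 1.0
        J[b + V_INHIB, b + I_INHIB] = 1.0
        J[b + V_PYR_INH, b + I_PYR_INH] = 1.0
        J[b + V_PYR, b + I_PYR_EXC] = 1.0
        J[b + V_PYR, b + I_PYR_INH] = -1.0
        for cur, volt, tau in ((I_STELLATE, V_STELLATE, te),
                               (I_PYR_EXC, V_PYR_EXC, te),
                               (I_INHIB, V_INHIB, te),
                               (I_PYR_INH, V_PYR_INH, ti)):
            J[b + cur, b + cur] = -2.0 / tau
            J[b + cur, b + volt] = -1.0 / tau ** 2
        # intrinsic sigmoid couplings
        J[b + I_STELLATE, b + V_PYR] += ke[k] * p.gamma1 * dsp[k]
        J[b + I_PYR_EXC, b + V_STELLATE] += ke[k] * p.gamma2 * dss[k]
        J[b + I_INHIB, b + V_PYR] += ke[k] * p.gamma3 * dsp[k]
        J[b + I_PYR_INH, b + V_INHIB] += ki * p.gamma4 * dsi[k]
        # extrinsic couplings from source pyramidal depolarizations
        for l in range(n):
            if GFL[k, l] != 0.0:
                J[b + I_STELLATE, N_STATES * l + V_PYR] += \
                    ke[k] * GFL[k, l] * dsp[l]
            if GBL[k, l] != 0.0:
                J[b + I_PYR_EXC, N_STATES * l + V_PYR] += \
                    ke[k] * GBL[k, l] * dsp[l]
                J[b + I_INHIB, N_STATES * l + V_PYR] += \
                    ke[k] * GBL[k, l] * dsp[l]
    return J


def state_delay_matrix(net: NetworkSpec, params: ERPParameters) -> np.ndarray:
    """State-to-state conduction delay matrix D (ms), shape (nu, nu).

    ``D[k, l]`` is the delay with which the equation of global state ``k``
    reads global state ``l``: zero within a population, ``d_intrinsic``
    between distinct populations of one region, and the extrinsic conduction
    delay between regions.
    """
    n = net.n_regions
    nu = net.n_states
    D = np.zeros((nu, nu))
    intra = (POPULATION[:, None] != POPULATION[None, :]) * params.d_intrinsic
    for k in range(n):
        for l in range(n):
            bk, bl = N_STATES * k, N_STATES * l
            if k == l:
                D[bk:bk + N_STATES, bl:bl + N_STATES] = intra
            else:
                D[bk:bk + N_STATES, bl:bl + N_STATES] = net.D_extrinsic[k, l]
    return D
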