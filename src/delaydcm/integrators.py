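"""Two integration schemes for the delayed neural-mass system.

``ta_integrate`` implements the fixed-step scheme used by standard DCM for
ERP: delayed states are replaced by a first-order Taylor expansion, which
turns the DDE system into an ODE system, and the ODE is advanced with a
local-linearization (matrix-exponential) update at the data sampling step.

``rk_integrate`` implements an adaptive embedded Runge-Kutta 2(3) solver for
DDEs (Bogacki-Shampine pair with its natural cubic-Hermite continuous
extension, the construction behind MATLAB's dde23): method of steps, delayed
values read from the continuous extension, and a fixed-point correction of
the step whenever the step size exceeds the smallest delay.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.linalg import expm

from .model import (
    BASELINE,
    ERPField,
    ERPParameters,
    NetworkSpec,
    jacobian_nodelay,
    state_delay_matrix,
)

__all__ = [
    "SolverOptions",
    "Trajectory",
    "IntegrationError",
    "delay_compensated_field",
    "ta_integrate",
    "rk_step",
    "rk_solve",
    "rk_integrate",
]


class IntegrationError(RuntimeError):
    """Raised when an integration diverges or cannot proceed."""


@dataclass
class SolverOptions:
    """Options shared by the two schemes.

    ``rel_tol``/``abs_tol`` control the adaptive scheme's weighted local
    error; defaults are 0.1% relative and 1e-6 absolute.  ``fixed_step`` is
    the Taylor scheme's step (defaults to the output sampling interval).
    """

    scheme: str = "rk"
    rel_tol: float = 1e-3
    abs_tol: float = 1e-6
    fixed_step: Optional[float] = None
    max_step: float = 4.0
    implicit_max_iter: int = 5
    max_steps: int = 200_000
    #: Taylor scheme linearization point: "step" re-evaluates the Jacobian
    #: (and the delay-compensation operator) at the current state of every
    #: step; "fixed" evaluates both once at the rest state, the cheap
    #: variant used by standard DCM software
    ta_jacobian: str = "step"

    def __post_init__(self):
        if self.scheme not in ("ta", "rk"):
            raise ValueError("scheme must be 'ta' or 'rk'")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")


def _hermite(s, h, x0, x1, f0, f1):
    """Cubic Hermite basis evaluation; s in [0, 1] on a step of width h."""
    s2 = s * s
    s3 = s2 * s
    return ((2 * s3 - 3 * s2 + 1) * x0 + (s3 - 2 * s2 + s) * h * f0
            + (3 * s2 - 2 * s3) * x1 + (s3 - s2) * h * f1)


@dataclass
class Trajectory:
    """Dense DDE/ODE solution with its continuous extension.

    ``mesh_times``/``states``/``slopes`` hold the accepted solver mesh and
    the field values there; ``sampled_times``/``sampled_states`` are the
    solution evaluated on the requested output grid.  Before ``mesh_times[0]``
    the solution is the constant initial state.
    """

    mesh_times: np.ndarray
    states: np.ndarray
    slopes: np.ndarray
    sampled_times: np.ndarray
    sampled_states: np.ndarray
    n_accepted: int = 0
    n_rejected: int = 0

    def evaluate(self, t) -> np.ndarray:
        """Continuous extension at time(s) ``t`` (ms)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        mt = self.mesh_times
        idx = np.clip(np.searchsorted(mt, t, side="right") - 1, 0,
                      len(mt) - 2)
        h = mt[idx + 1] - mt[idx]
        s = np.clip((t - mt[idx]) / h, 0.0, 1.0)
        out = _hermite(s[:, None], h[:, None], self.states[idx],
                       self.states[idx + 1], self.slopes[idx],
                       self.slopes[idx + 1])
        before = t <= mt[0]
        if before.any():
            out[before] = self.states[0]
        return out

    def to_frame(self):
        """Sampled solution as a pandas DataFrame (time + one state/col)."""
        import pandas as pd

        cols = {f"x{i}": self.sampled_states[:, i]
                for i in range(self.sampled_states.shape[1])}
        return pd.DataFrame({"time_ms": self.sampled_times, **cols})


# ---------------------------------------------------------------------------
# Taylor / local-linearization scheme (fixed step)
# ---------------------------------------------------------------------------

def _compensation(J: np.ndarray, D: np.ndarray):
    """LU-style factor helper: returns M = I + D o J, raising if singular."""
    M = np.eye(J.shape[0]) + D * J
    return M


def delay_compensated_field(t: float, x: np.ndarray, net: NetworkSpec,
                            params: ERPParameters,
                            condition: str = BASELINE) -> np.ndarray:
    """First-order Taylor delay compensation of the evolution function.

    Solves the self-consistency equation obtained by substituting
    ``x(t - d) ~= x(t) - d x'(t)`` into the delayed field:
    ``psi = (I + D o J)^-1 f(t, x)`` with all delayed lookups replaced by
    current values, where ``o`` is the elementwise product of the
    state-to-state delay matrix with the no-delay Jacobian.
    """
    x = np.asarray(x, dtype=float)
    fld = ERPField(net, params, condition)
    J = jacobian_nodelay(x, net, params, condition)
    D = state_delay_matrix(net, params)
    M = _compensation(J, D)
    try:
        return np.linalg.solve(M, fld.nodelay(t, x))
    except np.linalg.LinAlgError as exc:
        raise IntegrationError(
            "singular delay compensation matrix I + D o J "
            f"(max delay {D.max():.1f} ms)") from exc


def _phi1_times_tau(A: np.ndarray, tau: float) -> np.ndarray:
    """U = (expm(tau A) - I) A^-1 via the phi_1 matrix function.

    Computed from the exponential of the augmented matrix
    ``[[tau A, tau I], [0, 0]]`` whose top-right block is exactly U; this is
    well defined for singular A.
    """
    nu = A.shape[0]
    M = np.zeros((2 * nu, 2 * nu))
    M[:nu, :nu] = tau * A
    M[:nu, nu:] = tau * np.eye(nu)
    return expm(M)[:nu, nu:]


def ta_integrate(net: NetworkSpec, params: ERPParameters,
                 condition: str = BASELINE,
                 options: Optional[SolverOptions] = None,
                 t_grid: Optional[np.ndarray] = None) -> Trajectory:
    """Fixed-step local-linearization integration of the Taylor-compensated
    ODE system.

    At every step the update is ``x(t+tau) = x(t) + U psi(t, x)`` with
    ``U = (expm(tau J) - I) J^-1`` and ``J`` the Jacobian of the compensated
    field — re-evaluated at the current state each step, or frozen at the
    rest state with ``options.ta_jacobian = "fixed"``.  The step equals the
    output sampling interval.
    """
    options = options or SolverOptions(scheme="ta")
    t_grid = _default_grid(t_grid)
    tau = options.fixed_step or float(t_grid[1] - t_grid[0])
    if not np.allclose(np.diff(t_grid), tau):
        raise ValueError("ta_integrate requires a uniform output grid "
                         "matching the fixed step")
    fld = ERPField(net, params, condition)
    D = state_delay_matrix(net, params)
    nu = net.n_states
    xs = np.zeros((len(t_grid), nu))
    slopes = np.zeros_like(xs)
    x = np.zeros(nu)
    fixed = options.ta_jacobian == "fixed"
    M = U = None
    if fixed:
        J = jacobian_nodelay(x, net, params, condition)
        M = _compensation(J, D)
        try:
            Jpsi = np.linalg.solve(M, J)
        except np.linalg.LinAlgError as exc:
            raise IntegrationError(
                "singular delay compensation matrix I + D o J "
                f"(max delay {D.max():.1f} ms)") from exc
        U = _phi1_times_tau(Jpsi, tau)
    for i, t in enumerate(t_grid[:-1]):
        if not fixed:
            J = jacobian_nodelay(x, net, params, condition)
            M = _compensation(J, D)
            try:
                Jpsi = np.linalg.solve(M, J)
            except np.linalg.LinAlgError as exc:
                raise IntegrationError(
                    "singular delay compensation matrix I + D o J "
                    f"(max delay {D.max():.1f} ms)") from exc
            U = _phi1_times_tau(Jpsi, tau)
        try:
            psi = np.linalg.solve(M, fld.nodelay(t, x))
        except np.linalg.LinAlgError as exc:
            raise IntegrationError(
                "singular delay compensation matrix I + D o J "
                f"(max delay {D.max():.1f} ms)") from exc
        slopes[i] = psi
        x = x + U @ psi
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"divergence at step {i + 1} "
                                   f"(t = {t_grid[i + 1]:.1f} ms)")
        xs[i + 1] = x
    if not fixed:
        J = jacobian_nodelay(x, net, params, condition)
        M = _compensation(J, D)
    slopes[-1] = np.linalg.solve(M, fld.nodelay(t_grid[-1], x))
    return Trajectory(mesh_times=np.asarray(t_grid, dtype=float), states=xs,
                      slopes=slopes, sampled_times=np.asarray(t_grid, float),
                      sampled_states=xs, n_accepted=len(t_grid) - 1)


# ---------------------------------------------------------------------------
# Adaptive Runge-Kutta DDE scheme
# ---------------------------------------------------------------------------

def rk_step(t: float, x: np.ndarray, h: float, history: Callable,
            fieldfn: Callable, f1: Optional[np.ndarray] = None):
    """One embedded Bogacki-Shampine 2(3) step.

    ``history(tq)`` returns the full state at time ``tq``; the field is
    called as ``fieldfn(ts, xs, xlag)`` with ``xlag(d) = history(ts - d)``.
    Returns ``(x_next, error_estimate, (k1, k2, k3, k4))`` where ``k4`` is
    the slope at the step endpoint (FSAL).
    """

    def make_xlag(ts):
        return lambda d: history(ts - d)

    if f1 is None:
        f1 = fieldfn(t, x, make_xlag(t))
    k1 = f1
    k2 = fieldfn(t + 0.5 * h, x + 0.5 * h * k1, make_xlag(t + 0.5 * h))
    k3 = fieldfn(t + 0.75 * h, x + 0.75 * h * k2, make_xlag(t + 0.75 * h))
    x_next = x + h * (2.0 * k1 + 3.0 * k2 + 4.0 * k3) / 9.0
    k4 = fieldfn(t + h, x_next, make_xlag(t + h))
    err = h * (-5.0 * k1 / 72.0 + k2 / 12.0 + k3 / 9.0 - k4 / 8.0)
    return x_next, err, (k1, k2, k3, k4)


def rk_solve(fieldfn: Callable, nu: int, min_delay: Optional[float],
             options: SolverOptions, t_grid: np.ndarray,
             x0: Optional[np.ndarray] = None) -> Trajectory:
    """Method-of-steps adaptive integration of a constant-history DDE.

    ``fieldfn(t, x, xlag)`` evaluates the field with delayed lookups through
    ``xlag(delay)``; ``min_delay`` is the smallest positive delay the field
    uses (``None`` for a pure ODE).  History for ``t <= t0`` is the constant
    ``x0`` (rest state by default).  When a trial step is longer than
    ``min_delay``, delayed values fall inside the step and the step is
    iterated to self-consistency on an extrapolated Hermite polynomial.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    x0 = np.zeros(nu) if x0 is None else np.asarray(x0, dtype=float)
    mesh_t = [t0]
    mesh_x = [x0]
    rtol, atol = options.rel_tol, options.abs_tol

    # tentative polynomial for the step being attempted
    tent = {"t": t0, "h": 1.0, "x0": x0, "f0": None, "x1": x0, "f1": None,
            "used": False}

    def history(tq):
        if tq <= t0:
            return x0
        tm = mesh_t[-1]
        if tq <= tm:
            i = bisect_right(mesh_t, tq) - 1
            if i >= len(mesh_t) - 1:
                return mesh_x[-1]
            h = mesh_t[i + 1] - mesh_t[i]
            s = (tq - mesh_t[i]) / h
            return _hermite(s, h, mesh_x[i], mesh_x[i + 1], mesh_f[i],
                            mesh_f[i + 1])
        # inside (or at the end of) the current trial step
        tent["used"] = True
        s = (tq - tent["t"]) / tent["h"]
        return _hermite(s, tent["h"], tent["x0"], tent["f0"], tent["x1"],
                        tent["f1"])

    f0 = fieldfn(t0, x0, lambda d: history(t0 - d))
    mesh_f = [f0]
    h = min(options.max_step, 1.0,
            min_delay if min_delay is not None else np.inf,
            t_end - t0)
    n_acc = n_rej = 0
    t, x, f = t0, x0, f0
    just_rejected = False
    while t < t_end - 1e-12:
        if h < 1e-6:
            raise IntegrationError(
                f"step size underflow at t = {t:.3f} ms (stiffness or "
                "divergence)")
        h = min(h, t_end - t)
        implicit = min_delay is None or h > min_delay
        # predictor for the in-step polynomial: extrapolate the previous
        # mesh interval's cubic (falls back to Euler on the first step)
        if len(mesh_t) > 1:
            hp = mesh_t[-1] - mesh_t[-2]
            sp = (t + h - mesh_t[-2]) / hp
            x1_pred = _hermite(sp, hp, mesh_x[-2], mesh_x[-1], mesh_f[-2],
                               mesh_f[-1])
        else:
            x1_pred = x + h * f
        tent.update(t=t, h=h, x0=x, f0=f, x1=x1_pred, f1=f, used=False)
        converged = True
        if implicit:
            x_prev = None
            for _ in range(max(1, options.implicit_max_iter)):
                tent["used"] = False
                x_next, err, ks = rk_step(t, x, h, history, fieldfn, f1=f)
                if not tent["used"]:
                    break
                tent["x1"], tent["f1"] = x_next, ks[3]
                if x_prev is not None:
                    dn = np.max(np.abs(x_next - x_prev)
                                / (atol + rtol * np.abs(x_next)))
                    if dn < 0.1:
                        break
                x_prev = x_next
            else:
                converged = False
        else:
            x_next, err, ks = rk_step(t, x, h, history, fieldfn, f1=f)
        if not converged:
            n_rej += 1
            h *= 0.5
            just_rejected = True
            continue
        if not np.all(np.isfinite(x_next)):
            raise IntegrationError(f"divergence at t = {t:.3f} ms")
        scale = atol + rtol * np.maximum(np.abs(x), np.abs(x_next))
        errnorm = float(np.max(np.abs(err) / scale))
        if errnorm <= 1.0:
            t = t + h
            x, f = x_next, ks[3]
            mesh_t.append(t)
            mesh_x.append(x)
            mesh_f.append(f)
            n_acc += 1
            if n_acc + n_rej > options.max_steps:
                raise IntegrationError("maximum number of steps exceeded")
        else:
            n_rej += 1
        accepted = errnorm <= 1.0
        # no step growth straight after a rejection (standard controller)
        facmax = 1.0 if (just_rejected and accepted) else 5.0
        just_rejected = not accepted
        fac = 0.9 * errnorm ** (-1.0 / 3.0) if errnorm > 0 else facmax
        h = min(options.max_step, h * min(facmax, max(0.2, fac)))
    traj = Trajectory(
        mesh_times=np.array(mesh_t), states=np.array(mesh_x),
        slopes=np.array(mesh_f), sampled_times=t_grid,
        sampled_states=np.empty((len(t_grid), nu)),
        n_accepted=n_acc, n_rejected=n_rej)
    traj.sampled_states = traj.evaluate(t_grid)
    return traj


def rk_integrate(net: NetworkSpec, params: ERPParameters,
                 condition: str = BASELINE,
                 options: Optional[SolverOptions] = None,
                 t_grid: Optional[np.ndarray] = None) -> Trajectory:
    """Adaptive Runge-Kutta DDE integration of the ERP network model."""
    options = options or SolverOptions(scheme="rk")
    t_grid = _default_grid(t_grid)
    fld = ERPField(net, params, condition)
    return rk_solve(fld, net.n_states, fld.min_delay, options, t_grid)


def integrate(net: NetworkSpec, params: ERPParameters,
              condition: str = BASELINE,
              options: Optional[SolverOptions] = None,
              t_grid: Optional[np.ndarray] = None) -> Trajectory:
    """Dispatch to the scheme selected in ``options.scheme``."""
    options = options or SolverOptions()
    fn = ta_integrate if options.scheme == "ta" else rk_integrate
    return fn(net, params, condition, options, t_grid)


def _default_grid(t_grid):
    """Default output grid: 0-400 ms at 1 ms sampling."""
    if t_grid is None:
        return np.arange(0.0, 401.0, 1.0)
    return np.asarray(t_grid, dtype=float)
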