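"""Variational-Laplace inversion of a DCM on two-condition LFP data.

A fitted model (:class:`DCM`) bundles a network template (structure, prior-
mean strengths, allowed-modulation masks), the neural-mass constants and the
integration scheme.  Free parameters live on a latent scale with Gaussian
priors; every positive natural parameter is ``template * exp(latent)`` so the
latent prior mean 0 maps to the template value.  Inversion maximizes the
Laplace free energy

    F = accuracy - complexity

with a Levenberg-Marquardt-regularized Gauss-Newton scheme on the latent
parameters (finite-difference sensitivities) and a closed-form-style update
of a single observation-noise log-precision; steps are accepted only when F
increases, so the recorded trace is non-decreasing.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import BASELINE, MODULATED, ERPParameters, NetworkSpec
from .integrators import IntegrationError, SolverOptions, integrate
from .observation import SimulatedDataset, observe_lfp

__all__ = [
    "DCM",
    "PriorSpec",
    "FitControls",
    "Posterior",
    "default_priors",
    "apply_parameters",
    "predict_response",
    "free_energy",
    "vb_invert",
]

#: latent prior precision for dynamic parameters (DCM standard value)
DEFAULT_PRIOR_PRECISION = 16.0
#: prior expectation of extrinsic conduction delays, ms
DELAY_PRIOR_MS = 16.0
#: broad prior variance of the observation-noise log-precision
HYPER_PRIOR_VAR = 32.0


@dataclass
class DCM:
    """A fitted-model specification: structure + constants + integrator."""

    net: NetworkSpec
    params: ERPParameters
    options: SolverOptions = field(default_factory=SolverOptions)


@dataclass
class PriorSpec:
    """Gaussian priors over the latent parameter vector.

    ``names`` identifies each latent: ``("a", kind, k, l)`` baseline
    log-gain of an extrinsic connection, ``("b", kind, k, l)`` /
    ``("b", "intrinsic", k)`` log modulation gain, ``("delay", k, l)`` log
    extrinsic delay (prior mean maps to 16 ms), ``("tau_e",)``/``("tau_i",)``
    log synaptic time-constant scalings, ``("onset",)``/``("width",)`` log
    input-timing scalings.
    """

    names: list
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if not (len(self.names) == self.mean.size == self.var.size):
            raise ValueError("inconsistent prior sizes")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be > 0")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name) -> int:
        return self.names.index(tuple(name))

    def modulation_indices(self) -> np.ndarray:
        """Indices of latents that only affect the modulated condition."""
        return np.array([i for i, nm in enumerate(self.names)
                         if nm[0] == "b"], dtype=int)


def default_priors(net: NetworkSpec, free_baseline: bool = True,
                   free_delays: bool = True, free_tau: bool = True,
                   free_input: bool = True,
                   prior_precision: float = DEFAULT_PRIOR_PRECISION
                   ) -> PriorSpec:
    """Standard free-parameter set for a model template.

    Baseline extrinsic log-gains, log modulation gains on masked
    connections/regions, log extrinsic delays, log time-constant scalings
    and log input-timing scalings, all with prior mean 0 and variance
    ``1/prior_precision``.
    """
    names = []
    kinds = (("forward", net.A_forward), ("backward", net.A_backward),
             ("lateral", net.A_lateral))
    if free_baseline:
        for kind, A in kinds:
            for k, l in zip(*np.nonzero(A)):
                names.append(("a", kind, int(k), int(l)))
    for kind, mask in (("forward", net.mod_mask_forward),
                       ("backward", net.mod_mask_backward)):
        for k, l in zip(*np.nonzero(mask)):
            names.append(("b", kind, int(k), int(l)))
    for k in np.nonzero(net.mod_mask_intrinsic)[0]:
        names.append(("b", "intrinsic", int(k)))
    if free_delays:
        conn = (net.A_forward + net.A_backward + net.A_lateral) > 0
        for k, l in zip(*np.nonzero(conn)):
            names.append(("delay", int(k), int(l)))
    if free_tau:
        names += [("tau_e",), ("tau_i",)]
    if free_input:
        names += [("onset",), ("width",)]
    n = len(names)
    return PriorSpec(names=names, mean=np.zeros(n),
                     var=np.full(n, 1.0 / prior_precision))


def apply_parameters(theta: np.ndarray, priors: PriorSpec,
                     net: NetworkSpec, params: ERPParameters):
    """Map a latent vector to concrete (net, params) for simulation.

    Positive natural parameters are ``template * exp(latent)``; modulation
    latents populate ``params.modulation_factors`` as ``exp(latent)`` and
    extrinsic delays scale the 16 ms prior expectation.
    """
    theta = np.asarray(theta, dtype=float)
    net2 = copy.deepcopy(net)
    params2 = copy.deepcopy(params)
    mats = {"forward": net2.A_forward, "backward": net2.A_backward,
            "lateral": net2.A_lateral}
    mod = {"forward": np.ones_like(net.A_forward),
           "backward": np.ones_like(net.A_backward),
           "intrinsic": np.ones(net.n_regions)}
    any_mod = False
    for th, nm in zip(theta, priors.names):
        if nm[0] == "a":
            _, kind, k, l = nm
            mats[kind][k, l] *= math.exp(th)
        elif nm[0] == "b":
            any_mod = True
            if nm[1] == "intrinsic":
                mod["intrinsic"][nm[2]] = math.exp(th)
            else:
                mod[nm[1]][nm[2], nm[3]] = math.exp(th)
        elif nm[0] == "delay":
            _, k, l = nm
            net2.D_extrinsic[k, l] = DELAY_PRIOR_MS * math.exp(th)
        elif nm[0] == "tau_e":
            params2.tau_e = params.tau_e * math.exp(th)
        elif nm[0] == "tau_i":
            params2.tau_i = params.tau_i * math.exp(th)
        elif nm[0] == "onset":
            params2.input_onset = params.input_onset * math.exp(th)
        elif nm[0] == "width":
            params2.input_width = params.input_width * math.exp(th)
        else:
            raise ValueError(f"unknown parameter name {nm!r}")
    if any_mod:
        params2.modulation_factors = mod
    return net2, params2


def predict_response(theta: np.ndarray, dcm: DCM, priors: PriorSpec,
                     t_grid: np.ndarray,
                     conditions: Sequence[str] = (BASELINE, MODULATED)
                     ) -> np.ndarray:
    """Predicted (n_conditions, channels, samples) LFP series."""
    net2, params2 = apply_parameters(theta, priors, dcm.net, dcm.params)
    out = []
    for cond in conditions:
        traj = integrate(net2, params2, cond, dcm.options, t_grid)
        out.append(observe_lfp(traj, net2))
    return np.stack(out)


@dataclass
class Posterior:
    """Gaussian variational posterior with its free-energy decomposition."""

    names: list
    mean: np.ndarray
    cov: np.ndarray
    prior_mean: np.ndarray
    prior_var: np.ndarray
    noise_log_precision: float
    noise_log_precision_var: float
    free_energy: float
    accuracy: float
    complexity: float
    trace: list
    converged: bool
    n_iter: int

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def latent(self, name) -> tuple:
        """(posterior mean, sd) of one latent parameter."""
        i = self.names.index(tuple(name))
        return float(self.mean[i]), float(self.sd()[i])

    def natural(self, name, template: float = 1.0) -> float:
        """Posterior natural value ``template * exp(latent mean)``."""
        m, _ = self.latent(name)
        return template * math.exp(m)

    def credible_interval(self, name, template: float = 1.0,
                          level: float = 0.90) -> tuple:
        """Natural-scale equal-tail credibility interval."""
        from scipy.stats import norm

        m, s = self.latent(name)
        z = norm.ppf(0.5 + level / 2.0)
        return (template * math.exp(m - z * s),
                template * math.exp(m + z * s))


def _kl_gaussian(mq, Sq, mp, vp) -> float:
    """KL(q || p) between a full Gaussian q and a diagonal Gaussian p."""
    p = mq.size
    ivp = 1.0 / vp
    d = mq - mp
    sign, logdet_q = np.linalg.slogdet(Sq)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive "
                                    "definite")
    logdet_p = float(np.sum(np.log(vp)))
    return 0.5 * (float(np.sum(np.diag(Sq) * ivp)) + float(d @ (ivp * d))
                  - p + logdet_p - logdet_q)


def free_energy(residuals: np.ndarray, J: np.ndarray, posterior_mean,
                posterior_cov, priors: PriorSpec, noise_log_precision: float,
                noise_log_precision_var: float = 0.0,
                hyper_prior_mean: float = 0.0,
                hyper_prior_var: float = HYPER_PRIOR_VAR):
    """Laplace free energy split into accuracy and complexity.

    accuracy: expected Gaussian log-likelihood under the posterior (with the
    sensitivity-propagated trace term); complexity: KL from the parameter
    posterior to the prior plus the noise-hyperparameter KL.  Returns
    ``(F, accuracy, complexity)``.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    N = e.size
    mh, vh = noise_log_precision, noise_log_precision_var
    lam = math.exp(mh + 0.5 * vh)
    tr_term = float(np.sum((J @ posterior_cov) * J)) if J is not None else 0.0
    accuracy = (-0.5 * N * math.log(2.0 * math.pi) + 0.5 * N * mh
                - 0.5 * lam * (float(e @ e) + tr_term))
    complexity = _kl_gaussian(np.asarray(posterior_mean, float),
                              np.asarray(posterior_cov, float),
                              priors.mean, priors.var)
    if vh > 0.0:
        complexity += 0.5 * ((mh - hyper_prior_mean) ** 2 / hyper_prior_var
                             + vh / hyper_prior_var - 1.0
                             + math.log(hyper_prior_var / vh))
    return accuracy - complexity, accuracy, complexity


@dataclass
class FitControls:
    """Iteration controls of the variational scheme."""

    max_iter: int = 64
    f_tol: float = 0.01
    patience: int = 3
    fd_step: float = 1e-3
    damping: float = 0.01
    max_rejections: int = 8
    verbose: bool = False


def _jacobian(theta, dcm, priors, t_grid, base_pred, controls):
    """Forward-difference sensitivities of the stacked prediction.

    Modulation latents leave the baseline condition untouched, so their
    columns only re-integrate the modulated condition.
    """
    p = priors.n
    J = np.empty((base_pred.size, p))
    mod_idx = set(priors.modulation_indices().tolist())
    h = controls.fd_step
    for i in range(p):
        th = theta.copy()
        th[i] += h
        if i in mod_idx:
            pred_m = predict_response(th, dcm, priors, t_grid,
                                      conditions=(MODULATED,))
            pred = np.concatenate([base_pred[0][None], pred_m])
        else:
            pred = predict_response(th, dcm, priors, t_grid)
        J[:, i] = (pred.ravel() - base_pred.ravel()) / h
    return J


def vb_invert(dataset: SimulatedDataset, dcm: DCM,
              priors: Optional[PriorSpec] = None,
              controls: Optional[FitControls] = None) -> Posterior:
    """Fit a DCM to a two-condition dataset by variational Laplace.

    Returns the Gaussian posterior over latent parameters together with the
    free energy and its accuracy/complexity split.  The free-energy trace
    over accepted iterations is non-decreasing by construction (steps that
    would decrease F are rejected and the regularization increased).
    """
    priors = priors or default_priors(dcm.net)
    controls = controls or FitControls()
    y = dataset.observations()
    if y.shape[1] != dcm.net.n_regions:
        raise ValueError("dataset channel count does not match model")
    t_grid = dataset.times
    yv = y.ravel()
    N = yv.size
    P0 = np.diag(1.0 / priors.var)
    mu0 = priors.mean

    def full_eval(theta):
        """Prediction, sensitivities and the F-optimal noise precision."""
        pred = predict_response(theta, dcm, priors, t_grid)
        e = yv - pred.ravel()
        J = _jacobian(theta, dcm, priors, t_grid, pred, controls)
        lam = min(max(N / max(float(e @ e), 1e-12), 1e-8), 1e10)
        Sigma = None
        for _ in range(2):  # coupled lambda <-> Sigma refinement
            H = lam * (J.T @ J) + P0
            Sigma = np.linalg.inv(H)
            R = float(e @ e) + float(np.sum((J @ Sigma) * J))
            lam = min(max(N / R, 1e-8), 1e10)
        mh = math.log(lam) - 1.0 / N
        vh = 2.0 / N
        F, acc, comp = free_energy(e, J, theta, Sigma, priors, mh, vh)
        return dict(theta=theta, pred=pred, e=e, J=J, Sigma=Sigma, mh=mh,
                    vh=vh, lam=math.exp(mh + 0.5 * vh), F=F, acc=acc,
                    comp=comp)

    cur = full_eval(mu0.copy())
    trace = [cur["F"]]
    damping = controls.damping
    n_small = 0
    converged = False
    it = 0
    for it in range(1, controls.max_iter + 1):
        J, e = cur["J"], cur["e"]
        lam = cur["lam"]
        H = lam * (J.T @ J) + P0
        grad = lam * (J.T @ e) - P0 @ (cur["theta"] - mu0)
        accepted = False
        for _ in range(controls.max_rejections):
            Hd = H + damping * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                damping *= 8.0
                continue
            try:
                cand = full_eval(cur["theta"] + step)
            except IntegrationError:
                damping *= 8.0
                continue
            if np.isfinite(cand["F"]) and cand["F"] > cur["F"]:
                dF = cand["F"] - cur["F"]
                cur = cand
                damping = max(damping / 4.0, 1e-6)
                accepted = True
                break
            damping *= 8.0
        if not accepted:
            converged = True
            break
        trace.append(cur["F"])
        if controls.verbose:
            print(f"  iter {it:3d}  F = {cur['F']:.3f}  dF = {dF:.4f}")
        n_small = n_small + 1 if dF < controls.f_tol else 0
        if n_small >= controls.patience:
            converged = True
            break
    if not np.isfinite(cur["F"]):
        raise RuntimeError("non-finite free energy")
    return Posterior(
        names=list(priors.names), mean=cur["theta"], cov=cur["Sigma"],
        prior_mean=mu0, prior_var=priors.var.copy(),
        noise_log_precision=cur["mh"], noise_log_precision_var=cur["vh"],
        free_energy=cur["F"], accuracy=cur["acc"], complexity=cur["comp"],
        trace=trace, converged=converged, n_iter=it)
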