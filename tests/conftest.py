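"""Shared fixtures.

The expensive simulate-and-invert fixtures are session-scoped and shared by
the recovery and model-selection tests so each fit runs once.
"""

from __future__ import annotations

import numpy as np
import pytest

from delaydcm import (
    DCM,
    ERPParameters,
    ExperimentConfig,
    FitControls,
    SolverOptions,
    default_priors,
    generate_dataset,
    vb_invert,
)
from delaydcm.experiments import (
    model_variant,
    run_simulation1,
    sim1_network,
    sim1_parameters,
    sweep_network,
)

GRID_400 = np.arange(0.0, 401.0, 1.0)

RK_FIT = dict(scheme="rk", rel_tol=1e-2, max_step=2.0)
TA_FIT = dict(scheme="ta", rel_tol=1e-2)


@pytest.fixture(scope="session")
def sweep_trajectories():
    """Noiseless RK and TA solutions of the forward-only model, delays
    {4, 8, 16, 32} ms."""
    from delaydcm import integrate

    out = {}
    for d in (4.0, 8.0, 16.0, 32.0):
        net = sweep_network(d)
        params = ERPParameters()
        for scheme in ("ta", "rk"):
            traj = integrate(net, params, "baseline",
                             SolverOptions(scheme=scheme, rel_tol=1e-3),
                             GRID_400)
            out[(scheme, d)] = traj.sampled_states[:, [8, 17]].T
    return out


def _fit(ds, variant, fit_kw, max_iter=32):
    template = model_variant(sim1_network(16.0), variant)
    dcm = DCM(template, ERPParameters(), SolverOptions(**fit_kw))
    return vb_invert(ds, dcm, default_priors(template),
                     FitControls(max_iter=max_iter))


@pytest.fixture(scope="session")
def recovery_fits():
    """FB fits (both schemes) of 6 datasets with true delay 16 ms."""
    posts = {"rk": [], "ta": []}
    for seed in range(1, 7):
        ds = generate_dataset(sim1_network(16.0), sim1_parameters(),
                              SolverOptions(rel_tol=1e-3), 25.0, seed,
                              GRID_400)
        posts["rk"].append(_fit(ds, "FB", RK_FIT))
        posts["ta"].append(_fit(ds, "FB", TA_FIT))
    return posts


@pytest.fixture(scope="session")
def delay32_fits():
    """FB fits (both schemes) of 3 datasets with true delay 32 ms."""
    posts = {"rk": [], "ta": []}
    for seed in (11, 12, 13):
        ds = generate_dataset(sim1_network(32.0), sim1_parameters(),
                              SolverOptions(rel_tol=1e-3), 25.0, seed,
                              GRID_400)
        posts["rk"].append(_fit(ds, "FB", RK_FIT))
        posts["ta"].append(_fit(ds, "FB", TA_FIT))
    return posts


@pytest.fixture(scope="session")
def sim1_small_results():
    """Reduced 2-region study fitted with the adaptive scheme only."""
    cfg = ExperimentConfig.preset("sim1-small", seed=7)
    cfg.schemes = ("rk",)
    return run_simulation1(cfg)
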