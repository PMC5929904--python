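"""Random-effects Bayesian model comparison and posterior averaging.

Log model evidences (free energies) from independent datasets feed a
hierarchical Dirichlet model of model frequencies in the population; the
variational scheme below estimates the Dirichlet concentrations, the
expected posterior probability of each model and the exceedance probability
(the probability that a model is the most frequent one).  Posterior
parameter summaries are averaged across datasets weighted by each dataset's
posterior model probability (Bayesian model averaging).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, softmax

__all__ = [
    "BMSResult",
    "rfx_bms",
    "exceedance",
    "posterior_model_prob",
    "bma_average",
]


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies plus derived summaries."""

    models: list
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    per_dataset_model_prob: np.ndarray  # datasets x models

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "model": self.models,
            "alpha": self.alpha,
            "expected_prob": self.expected_prob,
            "exceedance_prob": self.exceedance_prob,
        })


def posterior_model_prob(log_evidences: np.ndarray) -> np.ndarray:
    """Per-dataset posterior model probabilities under a flat model prior.

    Softmax of the log evidences, computed with max-subtraction so that
    very unequal evidences neither overflow nor underflow.
    """
    F = np.asarray(log_evidences, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("log evidences must be finite")
    return softmax(F, axis=-1)


def rfx_bms(log_evidences: np.ndarray, models: Optional[Sequence] = None,
            alpha0: float = 1.0, tol: float = 1e-4, max_iter: int = 10_000,
            n_exceedance_samples: int = 1_000_000,
            seed: int = 0) -> BMSResult:
    """Random-effects Bayesian model comparison.

    ``log_evidences`` is a datasets x models matrix of free energies.  The
    variational update alternates per-dataset model responsibilities
    ``softmax(F_nm + digamma(alpha_m) - digamma(sum(alpha)))`` with the
    Dirichlet update ``alpha = alpha0 + column sums`` until the
    concentrations change by less than ``tol``.
    """
    F = np.atleast_2d(np.asarray(log_evidences, dtype=float))
    if not np.all(np.isfinite(F)):
        raise ValueError("log evidences must be finite")
    n_data, n_models = F.shape
    if models is None:
        models = [f"m{j + 1}" for j in range(n_models)]
    alpha = np.full(n_models, float(alpha0))
    for _ in range(max_iter):
        w = softmax(F + digamma(alpha) - digamma(alpha.sum()), axis=1)
        alpha_new = alpha0 + w.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    xp = exceedance(alpha, n_samples=n_exceedance_samples, seed=seed)
    return BMSResult(models=list(models), alpha=alpha,
                     expected_prob=alpha / alpha.sum(), exceedance_prob=xp,
                     per_dataset_model_prob=w)


def exceedance(alpha: np.ndarray, n_samples: int = 1_000_000,
               seed: int = 0) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior.

    Probability, per model, that its population frequency exceeds that of
    every competitor; estimated from normalized Gamma draws.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    rng = np.random.default_rng(seed)
    counts = np.zeros(alpha.size)
    # draw in blocks to bound memory
    block = 200_000
    left = int(n_samples)
    while left > 0:
        m = min(block, left)
        g = rng.standard_gamma(alpha, size=(m, alpha.size))
        idx, c = np.unique(np.argmax(g, axis=1), return_counts=True)
        counts[idx] += c
        left -= m
    return counts / float(n_samples)


def bma_average(means: np.ndarray, variances: np.ndarray,
                weights: np.ndarray):
    """Average posterior summaries across datasets.

    ``means``/``variances`` are datasets x parameters posterior summaries;
    ``weights`` (one per dataset, normalized internally) are typically the
    posterior probability of the chosen model for each dataset.  Returns the
    mixture mean and mixture variance
    ``sum w (v + m^2) - (sum w m)^2`` per parameter.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    variances = np.atleast_2d(np.asarray(variances, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()
    m = w @ means
    v = w @ (variances + means ** 2) - m ** 2
    return m, np.maximum(v, 0.0)
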