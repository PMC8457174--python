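"""Random-effects Bayesian model selection over per-subject log evidences.

Variational treatment of model frequencies with a Dirichlet prior:
subject-level responsibilities ``u_nk ∝ exp(log_evidence_nk +
digamma(alpha_k) - digamma(sum alpha))`` and count updates ``alpha_k =
alpha0 + sum_n u_nk`` are iterated to convergence.  Exceedance
probabilities (the posterior probability that model k is the most
frequent) are then estimated by Monte-Carlo sampling of the fitted
Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = ["BMSResult", "fit_bms", "exceedance_from_dirichlet"]


@dataclass(frozen=True)
class BMSResult:
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    n_subjects: int
    converged: bool
    n_iter: int


def fit_bms(
    log_evidence: np.ndarray,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Fit the random-effects model to an (n_subjects, n_models) evidence matrix."""
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be (N>=2, K>=2)")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence contains non-finite values")
    n, k = L.shape
    alpha = np.full(k, alpha0, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    xp = exceedance_from_dirichlet(alpha, n_draws=n_draws, seed=seed)
    return BMSResult(
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_prob=xp,
        n_subjects=n,
        converged=converged,
        n_iter=it,
    )


def exceedance_from_dirichlet(
    alpha: np.ndarray, n_draws: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo frequency with which each component of Dir(alpha) is maximal."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be positive and finite")
    rng = np.random.default_rng(seed)
    k = alpha.shape[0]
    counts = np.zeros(k, dtype=np.int64)
    # draw in blocks to bound memory
    block = 200_000
    remaining = int(n_draws)
    while remaining > 0:
        m = min(block, remaining)
        x = rng.dirichlet(alpha, size=m)
        winners = np.argmax(x, axis=1)
        counts += np.bincount(winners, minlength=k)
        remaining -= m
    return counts / n_draws
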