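"""Generators for correlated multi-modality trials and prevalence studies.

Multi-modality data need correlated binary outcomes per subject (the tests
are applied to the same patients).  We use Gaussian-copula thresholding:
latent exchangeable multivariate normals are dichotomised at the marginal
quantiles, with the latent correlation calibrated numerically so that the
binary (phi) correlation of each pair matches the requested value.  The
diseased block uses the sensitivity vector as marginals, the non-diseased
block the specificity vector; the blocks are independent.

Feasibility: a pair of Bernoulli margins (p_l, p_r) only admits correlations
between the Frechet bounds; an infeasible request raises with the admissible
range.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .datatypes import PrevalenceSpec, TestResultsTable

__all__ = [
    "generate_trial",
    "generate_prevalence_study",
    "feasible_correlation",
    "latent_correlation",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def feasible_correlation(p1: float, p2: float) -> tuple[float, float]:
    """Frechet bounds on the correlation of two Bernoulli variables."""
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    lo = (max(0.0, p1 + p2 - 1.0) - p1 * p2) / s
    hi = (min(p1, p2) - p1 * p2) / s
    return lo, hi


def _orthant(a: float, b: float, r: float) -> float:
    """P(Z1 <= a, Z2 <= b) for standard bivariate normal, correlation r."""
    cov = np.array([[1.0, r], [r, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [a, b]
        )
    )


@lru_cache(maxsize=4096)
def latent_correlation(p1: float, p2: float, rho: float) -> float:
    """Latent normal correlation reproducing binary correlation ``rho``.

    Solves P(X1=1, X2=1) = p1 p2 + rho * sqrt(p1 q1 p2 q2) for the latent
    correlation, where X_i = 1{Z_i <= Phi^-1(p_i)}; the joint probability is
    the bivariate normal orthant probability, strictly increasing in the
    latent correlation.
    """
    if rho == 0.0:
        return 0.0
    lo, hi = feasible_correlation(p1, p2)
    if not lo < rho < hi:
        raise ValueError(
            f"correlation {rho} infeasible for marginals ({p1}, {p2}); "
            f"admissible open range is ({lo:.4f}, {hi:.4f})"
        )
    a = stats.norm.ppf(p1)
    b = stats.norm.ppf(p2)
    target = p1 * p2 + rho * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(r: float) -> float:
        return _orthant(a, b, r) - target

    return float(optimize.brentq(gap, -0.9999, 0.9999, xtol=1e-10))


def _latent_matrix(p: np.ndarray, rho: float) -> np.ndarray:
    """Pairwise-calibrated latent correlation matrix (forced PSD if needed)."""
    M = p.size
    R = np.eye(M)
    for i in range(M):
        for j in range(i + 1, M):
            R[i, j] = R[j, i] = latent_correlation(float(p[i]), float(p[j]), rho)
    w, v = np.linalg.eigh(R)
    if w.min() < 1e-10:  # heterogeneous margins can break PSD slightly
        w = np.clip(w, 1e-10, None)
        R = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def sample_binary_block(
    p, rho: float, n: int, rng, size: int | None = None
) -> np.ndarray:
    """Draw correlated binary outcomes, shape (n, M) or (size, n, M).

    Marginal success probabilities ``p``; common pairwise binary correlation
    ``rho`` via the calibrated Gaussian copula.  ``size`` batches independent
    replicate trials in one call.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    rng = _rng(rng)
    M = p.size
    shape = (n, M) if size is None else (size, n, M)
    if M == 1 or rho == 0.0:
        return (rng.random(shape) < p).astype(np.int8)
    L = np.linalg.cholesky(_latent_matrix(p, rho))
    z = rng.standard_normal(shape) @ L.T
    return (z <= stats.norm.ppf(p)).astype(np.int8)


def generate_trial(
    se,
    sp,
    rho: float = 0.0,
    n1: int = 100,
    n0: int = 100,
    seed=None,
    modality_labels=None,
) -> TestResultsTable:
    """Simulate one diagnostic trial with M correlated modalities.

    ``n1`` diseased subjects with marginal positivity ``se`` and ``n0``
    non-diseased with marginal positivity ``1 - sp``; within each group the
    binary outcomes have pairwise correlation approximately ``rho``.
    """
    se = np.atleast_1d(np.asarray(se, dtype=float))
    sp = np.atleast_1d(np.asarray(sp, dtype=float))
    if se.size != sp.size:
        raise ValueError("se and sp must have equal length")
    if np.any((se <= 0) | (se >= 1) | (sp <= 0) | (sp >= 1)):
        raise ValueError("se and sp must lie strictly inside (0, 1)")
    rng = _rng(seed)
    x1 = sample_binary_block(se, rho, n1, rng)
    x0 = sample_binary_block(1.0 - sp, rho, n0, rng)
    gold = np.concatenate([np.ones(n1, dtype=np.int8), np.zeros(n0, dtype=np.int8)])
    ids = np.array([f"s{i + 1}" for i in range(n1 + n0)])
    return TestResultsTable(
        subject_id=ids,
        gold=gold,
        results=np.vstack([x1, x0]),
        modality_labels=modality_labels,
    )


def generate_prevalence_study(
    pi: float,
    m: int,
    seed=None,
    label: str = "simulated",
    max_retries: int = 1000,
) -> PrevalenceSpec:
    """Simulate a prevalence study: ``k ~ Binomial(m, pi)`` diseased of ``m``.

    Boundary draws (k = 0 or k = m) are redrawn, since a boundary prevalence
    breaks the open-interval assumption of the asymptotics; the number of
    redraws is recorded in ``meta['boundary_resamples']``.  If no interior
    draw is possible (e.g. ``m = 1``) a ValueError is raised.
    """
    if not 0 < pi < 1:
        raise ValueError("pi must lie strictly inside (0, 1)")
    rng = _rng(seed)
    resamples = 0
    for _ in range(max_retries):
        k = int(rng.binomial(m, pi))
        if 0 < k < m:
            break
        resamples += 1
    else:
        raise ValueError(
            f"could not draw an interior prevalence count with m={m} after "
            f"{max_retries} attempts (boundary counts violate the "
            "open-interval assumption)"
        )
    pi_hat = k / m
    spec = PrevalenceSpec(
        group_labels=[label],
        k=np.array([float(k)]),
        m=np.array([float(m)]),
        pi_hat=np.array([pi_hat]),
        var_pi=np.array([pi_hat * (1 - pi_hat) / m]),
        fixed=np.array([False]),
    )
    spec.meta["boundary_resamples"] = resamples
    return spec
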