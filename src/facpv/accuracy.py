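"""Sensitivity/specificity estimation with joint estimator covariance.

For subject-level data the estimators are the usual proportions
``se_m = TP_m / n1`` and ``sp_m = TN_m / n0``.  Because all modalities are
applied to the same subjects, the estimators are correlated within the
diseased and within the non-diseased group:

    Cov(se_l, se_r) = (P_lr - se_l se_r) / n1,

where ``P_lr`` is the proportion of diseased subjects positive on both
modality ``l`` and ``r`` (the multivariate-Bernoulli joint success
probability); analogously for specificity from joint negatives among the
non-diseased.  The two groups are independent, so se and sp estimators are
uncorrelated.  The plug-in (maximum-likelihood) denominator ``n_i`` is used,
not ``n_i - 1``.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AccuracySummary, TestResultsTable

__all__ = ["estimate_accuracy", "summary_accuracy"]


def _proportion_cov(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance of column means of a binary matrix."""
    x = np.asarray(x, dtype=float)  # guard against integer overflow in x'x
    n = x.shape[0]
    p = x.mean(axis=0)
    joint = (x.T @ x) / n
    return p, (joint - np.outer(p, p)) / n


def estimate_accuracy(table: TestResultsTable) -> AccuracySummary:
    """Estimate se/sp vectors and their full covariance from subject data."""
    diseased = table.results[table.gold == 1]
    healthy = 1 - table.results[table.gold == 0]
    se, cov_se = _proportion_cov(diseased)
    sp, cov_sp = _proportion_cov(healthy)
    return AccuracySummary(
        se=se,
        sp=sp,
        n1=table.n1,
        n0=table.n0,
        cov_se=cov_se,
        cov_sp=cov_sp,
        modality_labels=list(table.modality_labels),
        has_cross_covariance=True,
    )


def summary_accuracy(se, sp, n1: int, n0: int, modality_labels=None) -> AccuracySummary:
    """Build an :class:`AccuracySummary` from marginal summary statistics.

    Used when the original subject-level data are unavailable.  Only the
    binomial variances ``se(1-se)/n1`` and ``sp(1-sp)/n0`` can be formed;
    cross-modality covariances are unknown and marked absent (NaN), so
    multi-modality hypothesis tests and difference intervals are refused
    downstream.  Per-modality confidence intervals remain available.
    """
    se = np.atleast_1d(np.asarray(se, dtype=float))
    sp = np.atleast_1d(np.asarray(sp, dtype=float))
    if np.any((se <= 0) | (se >= 1) | (sp <= 0) | (sp >= 1)):
        raise ValueError("summary se and sp must lie strictly inside (0, 1)")
    M = se.size
    cov_se = np.full((M, M), np.nan)
    cov_sp = np.full((M, M), np.nan)
    np.fill_diagonal(cov_se, se * (1 - se) / n1)
    np.fill_diagonal(cov_sp, sp * (1 - sp) / n0)
    return AccuracySummary(
        se=se,
        sp=sp,
        n1=n1,
        n0=n0,
        cov_se=cov_se,
        cov_sp=cov_sp,
        modality_labels=modality_labels,
        has_cross_covariance=(M == 1),
    )
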