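"""Hypothesis tests and contrast intervals for factorial predictive values.

The global hypothesis "all modalities have the same predictive value in this
risk group", H0: T p = 0 with the centering matrix T = I - (1/M) 1 1', is
tested with the ANOVA-type statistic (ATS)

    ATS = p' T p / tr(T C),          f = [tr(T C)]^2 / tr[(T C)^2],

where C is the finite-sample delta-method covariance of the estimates; under
H0 the statistic is referred to a scaled chi-square chi2(f)/f (Box-type
approximation with estimated degrees of freedom).  On the logit scale the
same construction is applied to logit(p) with covariance D C D,
D = diag(1 / (p (1-p))).

Arbitrary linear contrasts c'p (differences, reader averages, ...) get Wald
intervals from the quadratic form c' C c; their t degrees of freedom reuse
the Satterthwaite combination of the three variance components.

p-values are reported per group/side without multiplicity adjustment.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logit

from .datatypes import ATSResult, PVResult
from .predictive import _contrast_variance, _pv_component_dfs, _satterthwaite

__all__ = ["ats_test", "contrast_interval", "centering_matrix"]


def centering_matrix(M: int) -> np.ndarray:
    """The one-way contrast projection T = I_M - (1/M) 1 1'."""
    return np.eye(M) - np.full((M, M), 1.0 / M)


def _require_cross(pv: PVResult, what: str) -> None:
    if pv.n_modalities > 1 and not pv.accuracy.has_cross_covariance:
        raise ValueError(
            f"{what} needs the cross-modality covariance of the accuracy "
            "estimators, which is unavailable for summary-level input "
            "(se/sp vectors without subject-level data); supply the original "
            "trial data instead"
        )


def ats_test(
    pv: PVResult,
    T: np.ndarray | None = None,
    scale: str = "additive",
) -> ATSResult:
    """ANOVA-type test of H0: T p = 0 for one risk group and side.

    Parameters
    ----------
    pv : PVResult
        Must come from subject-level data (full covariance) with M >= 2.
    T : ndarray, optional
        Symmetric idempotent contrast projection; defaults to the centering
        matrix testing equality of all modalities.  A supplied matrix is
        symmetrised and verified to be a projection.
    scale : {"additive", "logit"}
        Test on the original or the logit scale.
    """
    M = pv.n_modalities
    if M < 2:
        raise ValueError("the ANOVA-type test needs at least two modalities")
    _require_cross(pv, "the ANOVA-type test")
    if scale not in ("additive", "logit"):
        raise ValueError("scale must be 'additive' or 'logit'")

    if T is None:
        T = centering_matrix(M)
    else:
        T = np.asarray(T, dtype=float)
        if T.shape != (M, M):
            raise ValueError(f"contrast matrix must be {M}x{M}")
        T = (T + T.T) / 2.0
        if not np.allclose(T @ T, T, atol=1e-10):
            raise ValueError("contrast matrix must be idempotent (a projection)")

    est = pv.estimates
    cov = pv.cov
    if scale == "logit":
        if np.any(pv.degenerate):
            raise ValueError(
                "logit-scale test undefined: boundary point estimate(s)"
            )
        D = np.diag(1.0 / (est * (1.0 - est)))
        est = logit(est)
        cov = D @ cov @ D

    TC = T @ cov
    trace = float(np.trace(TC))
    if not trace > 0:
        raise ValueError(
            "degenerate covariance: tr(T C) is zero, the ANOVA-type statistic "
            "is undefined (e.g. identical duplicated modalities)"
        )
    statistic = float(est @ T @ est) / trace
    f = trace**2 / float(np.trace(TC @ TC))
    # chi2(f)/f reference: P(ATS > x) = P(chi2_f > f x)
    p_value = float(stats.chi2.sf(statistic * f, f))
    return ATSResult(
        statistic=statistic,
        df=f,
        p_value=p_value,
        contrast=T,
        scale=scale,
        side=pv.side,
        group_label=pv.group_label,
    )


def contrast_interval(
    pv: PVResult,
    c,
    method: str = "additive-normal",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Wald interval for the linear contrast ``c' p`` of one group's PVs.

    Supports ``additive-normal``, ``additive-t`` and ``mercaldo-additive``
    (a logit transform of a signed contrast is not defined).  With
    ``c = e_i - e_j`` this is the two-modality difference interval.
    """
    if method not in ("additive-normal", "additive-t", "mercaldo-additive"):
        raise ValueError(
            "contrast intervals support additive methods only, got "
            f"{method!r}"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    c = np.asarray(c, dtype=float)
    if c.shape != (pv.n_modalities,):
        raise ValueError(f"contrast must have length {pv.n_modalities}")
    if np.count_nonzero(c) > 1:
        _require_cross(pv, "a multi-modality contrast")

    center = float(c @ pv.estimates)
    fixed = method.startswith("mercaldo")
    c_se, c_sp, c_pi = _contrast_variance(pv, c, fixed)
    var = c_se + c_sp + c_pi
    if var < 0 and var > -1e-15:  # numeric noise at exact degeneracy
        var = 0.0
    sd = np.sqrt(var)
    if method == "additive-t" and var > 0:
        # component dfs: conservative minimum over the modalities involved
        nu_se, nu_sp, nu_pi = _pv_component_dfs(pv)
        active = c != 0
        nu = _satterthwaite(
            c_se,
            c_sp,
            c_pi,
            float(np.min(nu_se[active])),
            float(np.min(nu_sp[active])),
            nu_pi,
        )
        q = float(stats.t.ppf(1 - alpha / 2, nu))
    else:
        q = float(stats.norm.ppf(1 - alpha / 2))
    return center - q * sd, center + q * sd
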