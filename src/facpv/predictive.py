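"""Predictive values per risk group with delta-method uncertainty.

Bayes' theorem expresses the positive and negative predictive value of a
test as functions of sensitivity, specificity and the pre-test probability
(prevalence) of disease in the patient's risk group:

    PPV = se * pi / (se * pi + (1 - sp) * (1 - pi))
    NPV = sp * (1 - pi) / (sp * (1 - pi) + (1 - se) * pi)

Plugging in the estimators of se, sp and pi yields plug-in estimators whose
covariance follows from the multivariate delta method: with gradient ``g_m``
of the transformation at modality ``m``,

    Cov(p_l, p_r) = g_l' D_lr g_r,

where the 3x3 block ``D_lr`` collects ``Cov(se_l, se_r)``, ``Cov(sp_l,
sp_r)`` and ``Var(pi)`` (the prevalence estimate is shared across modalities,
hence fully correlated between them, and independent of the accuracy study).
Setting ``Var(pi) = 0`` recovers the classical fixed-prevalence (known-pi)
variance.

Four interval flavours are built on top: additive (plain Wald) and logistic
(logit-scale, range-preserving), each with a normal or a t quantile; the t
degrees of freedom come from a Satterthwaite combination of the three
binomial variance components.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .datatypes import (
    AccuracySummary,
    IntervalSet,
    PrevalenceSpec,
    PVResult,
)

__all__ = [
    "ppv",
    "npv",
    "pv_gradient",
    "pv_covariance",
    "confidence_interval",
    "difference_interval",
    "t_degrees_of_freedom",
]


# ---------------------------------------------------------------------------
# Point transformations and gradients (array-safe internals + checked API)
# ---------------------------------------------------------------------------

def _ppv(se, sp, pi):
    num = se * pi
    den = num + (1 - sp) * (1 - pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def _npv(se, sp, pi):
    num = sp * (1 - pi)
    den = num + (1 - se) * pi
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def _pv(se, sp, pi, side: str):
    return _ppv(se, sp, pi) if side == "ppv" else _npv(se, sp, pi)


def _grad_ppv(se, sp, pi):
    A = se * pi
    B = (1 - sp) * (1 - pi)
    S2 = (A + B) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dse = pi * B / S2
        dsp = A * (1 - pi) / S2
        dpi = (se * B + A * (1 - sp)) / S2
    return dse, dsp, dpi


def _grad_npv(se, sp, pi):
    A = sp * (1 - pi)
    B = (1 - se) * pi
    S2 = (A + B) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        dse = A * pi / S2
        dsp = (1 - pi) * B / S2
        dpi = -(sp * B + A * (1 - se)) / S2
    return dse, dsp, dpi


def _grad(se, sp, pi, side: str):
    return _grad_ppv(se, sp, pi) if side == "ppv" else _grad_npv(se, sp, pi)


def _check_unit_open(**kwargs) -> None:
    for name, value in kwargs.items():
        v = np.asarray(value, dtype=float)
        if np.any((v <= 0) | (v >= 1)):
            raise ValueError(f"{name} must lie strictly inside (0, 1)")


def ppv(se, sp, pi):
    """Positive predictive value by Bayes' theorem.

    All arguments must lie strictly inside (0, 1); scalars or broadcastable
    arrays are accepted.
    """
    _check_unit_open(se=se, sp=sp, pi=pi)
    return _ppv(np.asarray(se, float), np.asarray(sp, float), np.asarray(pi, float))[()]


def npv(se, sp, pi):
    """Negative predictive value by Bayes' theorem (domain as :func:`ppv`)."""
    _check_unit_open(se=se, sp=sp, pi=pi)
    return _npv(np.asarray(se, float), np.asarray(sp, float), np.asarray(pi, float))[()]


def pv_gradient(se: float, sp: float, pi: float, side: str = "ppv") -> np.ndarray:
    """Analytic gradient of PPV or NPV with respect to ``(se, sp, pi)``."""
    _check_unit_open(se=se, sp=sp, pi=pi)
    side = side.lower()
    if side not in ("ppv", "npv"):
        raise ValueError("side must be 'ppv' or 'npv'")
    return np.array(_grad(float(se), float(sp), float(pi), side))


# ---------------------------------------------------------------------------
# Delta-method covariance
# ---------------------------------------------------------------------------

def pv_covariance(
    acc: AccuracySummary,
    prev: PrevalenceSpec,
    group: str | int,
    side: str = "ppv",
) -> PVResult:
    """Predictive-value vector and delta-method covariance for one risk group.

    Returns a :class:`PVResult` whose ``cov`` is the finite-sample covariance
    of the plug-in estimators, decomposed into the three additive components
    (se, sp, prevalence) stored in ``components``.
    """
    side = side.lower()
    if side not in ("ppv", "npv"):
        raise ValueError("side must be 'ppv' or 'npv'")
    g = prev.index(group)
    pi = float(prev.pi_hat[g])
    var_pi = float(prev.var_pi[g])

    est = _pv(acc.se, acc.sp, pi, side)
    dse, dsp, dpi = _grad(acc.se, acc.sp, pi, side)
    c_se = np.outer(dse, dse) * acc.cov_se
    c_sp = np.outer(dsp, dsp) * acc.cov_sp
    c_pi = var_pi * np.outer(dpi, dpi)
    return PVResult(
        group_label=prev.group_labels[g],
        side=side,
        estimates=est,
        cov=c_se + c_sp + c_pi,
        components={"se": c_se, "sp": c_sp, "pi": c_pi},
        accuracy=acc,
        pi=pi,
        var_pi=var_pi,
        m_g=float(prev.m[g]),
        modality_labels=list(acc.modality_labels),
    )


# ---------------------------------------------------------------------------
# Degrees of freedom (Welch-Satterthwaite over the three binomial components)
# ---------------------------------------------------------------------------

def _component_df(p, n):
    """Moment-matched chi-square df of the variance estimator p(1-p)/n.

    By the delta method, Var[p_hat (1-p_hat)] ~ (1-2p)^2 p(1-p)/n, so
    matching the first two moments of a scaled chi-square gives

        nu = 2 n p (1-p) / (1-2p)^2,

    which tends to infinity as p -> 1/2 (the variance estimator is then
    first-order exact) and shrinks towards 0 at extreme p.
    """
    p = np.asarray(p, float)
    num = 2.0 * n * p * (1.0 - p)
    den = (1.0 - 2.0 * p) ** 2
    with np.errstate(divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)


def _satterthwaite(c_se, c_sp, c_pi, nu_se, nu_sp, nu_pi):
    """Welch combination nu = v^2 / sum_i c_i^2 / nu_i (vectorised).

    Returns inf where the denominator vanishes but the total variance does
    not (the t quantile then degenerates to the normal one) and NaN where
    the total variance itself is zero (boundary estimate, t not applicable).
    """
    arrays = [np.asarray(a, float) for a in (c_se, c_sp, c_pi)]
    total = sum(arrays)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = sum(
            np.where(nu > 0, c**2 / nu, np.inf * c**2)
            for c, nu in zip(arrays, (nu_se, nu_sp, nu_pi))
        )
        nu = np.where(den > 0, total**2 / np.where(den > 0, den, 1.0), np.inf)
    return np.where(total > 0, nu, np.nan)


def _pv_component_dfs(pv: PVResult):
    """Per-source component dfs at the plug-in estimates (se, sp, pi)."""
    acc = pv.accuracy
    nu_se = _component_df(acc.se, acc.n1)
    nu_sp = _component_df(acc.sp, acc.n0)
    if pv.var_pi > 0:
        nu_pi = float(_component_df(pv.pi, pv.m_g))
    else:
        nu_pi = np.inf  # fixed prevalence contributes no estimation noise
    return nu_se, nu_sp, nu_pi


def t_degrees_of_freedom(pv: PVResult, modality: int = 0) -> float:
    """Satterthwaite-type t degrees of freedom for one modality's estimator.

    Combines the three variance contributions ``c_x = (df/dx)^2 Var(x_hat)``
    of sensitivity, specificity and prevalence by the Welch rule

        nu = (c_se + c_sp + c_pi)^2 / (sum_x c_x^2 / nu_x),

    where ``nu_x = 2 n_x p_x (1 - p_x) / (1 - 2 p_x)^2`` is the
    moment-matched df of the underlying binomial variance estimator
    (see :func:`_component_df`).  NaN is returned when every component
    vanishes (degenerate estimate); inf when the denominator vanishes with
    positive variance (t reduces to the normal approximation).
    """
    m = pv.accuracy.modality_index(modality)
    nu_se, nu_sp, nu_pi = _pv_component_dfs(pv)
    nu = _satterthwaite(
        pv.components["se"][m, m],
        pv.components["sp"][m, m],
        pv.components["pi"][m, m],
        nu_se[m],
        nu_sp[m],
        nu_pi,
    )
    return float(nu)


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

def _method_parts(method: str) -> tuple[bool, bool]:
    """-> (fixed_prevalence_variance, use_t_quantile)."""
    fixed = method.startswith("mercaldo")
    use_t = method.endswith("-t")
    return fixed, use_t


def confidence_interval(
    pv: PVResult, method: str = "additive-normal", alpha: float = 0.05
) -> IntervalSet:
    """Two-sided (1 - alpha) confidence intervals for each modality.

    Methods
    -------
    ``additive-normal`` / ``additive-t``
        Wald interval ``p +- q * sd(p)``; not clipped to [0, 1].
    ``logistic-normal`` / ``logistic-t``
        Delta method on the logit scale, back-transformed; range-preserving
        by construction but undefined (``failed``) at boundary estimates.
    ``mercaldo-additive`` / ``mercaldo-logistic``
        Same constructions with the prevalence treated as known (its
        variance contribution removed); normal quantile.

    A t method's degrees of freedom are the Satterthwaite values of
    :func:`t_degrees_of_freedom`; the t interval fails where the df are
    undefined (variance estimated as 0, i.e. boundary estimates).
    """
    if method not in (
        "additive-normal",
        "additive-t",
        "logistic-normal",
        "logistic-t",
        "mercaldo-additive",
        "mercaldo-logistic",
    ):
        raise ValueError(f"unknown interval method {method!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fixed, use_t = _method_parts(method)
    logistic = "logistic" in method

    c_se = np.diag(pv.components["se"]).copy()
    c_sp = np.diag(pv.components["sp"]).copy()
    c_pi = np.zeros_like(c_se) if fixed else np.diag(pv.components["pi"]).copy()
    var = c_se + c_sp + c_pi
    sd = np.sqrt(var)
    est = pv.estimates
    M = est.size

    df = None
    if use_t:
        nu_se, nu_sp, nu_pi = _pv_component_dfs(pv)
        df = _satterthwaite(c_se, c_sp, c_pi, nu_se, nu_sp, nu_pi)
        q = np.where(np.isnan(df), np.nan, stats.t.ppf(1 - alpha / 2, df))
    else:
        q = np.full(M, stats.norm.ppf(1 - alpha / 2))

    boundary = (est <= 0) | (est >= 1) | ~np.isfinite(est)
    failed = np.zeros(M, dtype=bool)
    if logistic or use_t:
        failed |= boundary
    if use_t:
        failed |= ~np.isfinite(np.asarray(df, float))

    with np.errstate(invalid="ignore", divide="ignore"):
        if logistic:
            scale = sd / (est * (1 - est))
            lower = expit(logit(est) - q * scale)
            upper = expit(logit(est) + q * scale)
        else:
            lower = est - q * sd
            upper = est + q * sd
    lower = np.where(failed, np.nan, lower)
    upper = np.where(failed, np.nan, upper)
    return IntervalSet(
        method=method,
        alpha=alpha,
        estimates=est.copy(),
        lower=lower,
        upper=upper,
        failed=failed,
        df=df,
        modality_labels=list(pv.modality_labels),
    )


def _contrast_variance(pv: PVResult, c: np.ndarray, fixed: bool):
    comps = []
    for key in ("se", "sp", "pi"):
        mat = pv.components[key]
        if key == "pi" and fixed:
            comps.append(0.0)
        else:
            comps.append(float(c @ mat @ c))
    return comps


def difference_interval(
    pv: PVResult,
    m1: str | int,
    m2: str | int,
    method: str = "additive-normal",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Confidence interval for the difference of two modalities' PV.

    Variance is ``v[m1,m1] + v[m2,m2] - 2 v[m1,m2]``, which requires the
    cross-modality covariance and therefore subject-level input (unless the
    two indices coincide).  Only additive methods apply to a difference.
    """
    i = pv.accuracy.modality_index(m1)
    j = pv.accuracy.modality_index(m2)
    c = np.zeros(pv.n_modalities)
    c[i] += 1.0
    c[j] -= 1.0
    from .inference import contrast_interval  # local import avoids a cycle

    return contrast_interval(pv, c, method=method, alpha=alpha)
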