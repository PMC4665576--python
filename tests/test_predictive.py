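"""Predictive values, delta-method covariance and the interval variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import facpv
from facpv.predictive import (
    _satterthwaite,
    confidence_interval,
    difference_interval,
    npv,
    ppv,
    pv_covariance,
    pv_gradient,
    t_degrees_of_freedom,
)

SE, SP = 140 / 164, 114 / 127

# Printed CAD results: group -> (ppv, npv) point estimates, 3 dp.
TABLE5_POINTS = {
    "nonanginal": (0.614, 0.970),
    "atypical": (0.892, 0.860),
    "typical": (0.985, 0.434),
}

# group -> side -> method -> (lower, upper), 3 dp.
TABLE5_INTERVALS = {
    ("nonanginal", "ppv"): {
        "additive-normal": (0.483, 0.744),
        "logistic-normal": (0.478, 0.733),
        "additive-t": (0.480, 0.747),
        "logistic-t": (0.474, 0.736),
    },
    ("nonanginal", "npv"): {
        "additive-normal": (0.958, 0.982),
        "logistic-normal": (0.955, 0.980),
        "additive-t": (0.957, 0.982),
        "logistic-t": (0.955, 0.980),
    },
    ("atypical", "ppv"): {
        "additive-normal": (0.842, 0.943),
        "logistic-normal": (0.830, 0.933),
        "additive-t": (0.840, 0.945),
        "logistic-t": (0.828, 0.935),
    },
    ("atypical", "npv"): {
        "additive-normal": (0.814, 0.907),
        "logistic-normal": (0.807, 0.901),
        "additive-t": (0.814, 0.907),
        "logistic-t": (0.807, 0.901),
    },
    ("typical", "ppv"): {
        "additive-normal": (0.977, 0.993),
        "logistic-normal": (0.975, 0.991),
        "additive-t": (0.977, 0.993),
        "logistic-t": (0.975, 0.991),
    },
    ("typical", "npv"): {
        "additive-normal": (0.336, 0.532),
        "logistic-normal": (0.339, 0.533),
        "additive-t": (0.335, 0.533),
        "logistic-t": (0.338, 0.534),
    },
}

unit = st.floats(0.02, 0.98)


@pytest.mark.parametrize("group,expected", TABLE5_POINTS.items())
def test_cad_point_estimates(cad_accuracy, cad_prevalence, group, expected):
    """The six risk-group PPV/NPV values of the CAD example, to 3 dp."""
    pi = cad_prevalence.pi_hat[cad_prevalence.index(group)]
    assert round(float(ppv(SE, SP, pi)), 3) == expected[0]
    assert round(float(npv(SE, SP, pi)), 3) == expected[1]


def test_uninformative_test_returns_prevalence():
    """With sp = 1 - se the test carries no information: PPV = pi, NPV = 1 - pi."""
    assert ppv(0.7, 0.3, 0.2) == pytest.approx(0.2)
    assert npv(0.7, 0.3, 0.2) == pytest.approx(0.8)


def test_domain_errors():
    for bad in (0.0, 1.0, -0.1, 1.3):
        with pytest.raises(ValueError):
            ppv(bad, 0.9, 0.2)
        with pytest.raises(ValueError):
            npv(0.9, 0.9, bad)


@given(se=unit, sp=unit, pi=unit)
@settings(max_examples=200, deadline=None)
def test_bayes_consistency_identity(se, sp, pi):
    """ppv * P(T+) = se * pi (law of total probability)."""
    p_pos = se * pi + (1 - sp) * (1 - pi)
    assert ppv(se, sp, pi) * p_pos == pytest.approx(se * pi, rel=1e-12)


@given(se=unit, sp=unit, pi=unit, d=st.floats(1e-4, 0.01))
@settings(max_examples=200, deadline=None)
def test_monotonicity(se, sp, pi, d):
    """PPV strictly increases in se, sp and pi; NPV strictly decreases in pi."""
    assert ppv(min(se + d, 0.99), sp, pi) > ppv(se, sp, pi)
    assert ppv(se, min(sp + d, 0.99), pi) > ppv(se, sp, pi)
    assert ppv(se, sp, min(pi + d, 0.99)) > ppv(se, sp, pi)
    assert npv(se, sp, min(pi + d, 0.99)) < npv(se, sp, pi)


@pytest.mark.parametrize("side", ["ppv", "npv"])
def test_gradient_matches_finite_differences(side, rng):
    """Analytic gradient vs central differences, 100 random points, 1e-6 rel."""
    f = ppv if side == "ppv" else npv
    h = 1e-6
    pts = 0.05 + 0.9 * rng.random((100, 3))
    for se, sp, pi in pts:
        grad = pv_gradient(se, sp, pi, side)
        fd = np.array(
            [
                (f(se + h, sp, pi) - f(se - h, sp, pi)) / (2 * h),
                (f(se, sp + h, pi) - f(se, sp - h, pi)) / (2 * h),
                (f(se, sp, pi + h) - f(se, sp, pi - h)) / (2 * h),
            ]
        )
        scale = np.maximum(np.abs(fd), 1e-3)
        np.testing.assert_allclose(grad / scale, fd / scale, atol=1e-6)


def test_gradient_perfect_specificity_limit():
    """As sp -> 1 the PPV saturates at 1, so d(PPV)/d(se) -> 0."""
    assert pv_gradient(0.8, 1 - 1e-9, 0.3, "ppv")[0] == pytest.approx(0.0, abs=1e-6)


def test_nonanginal_ppv_variance(cad_accuracy, cad_prevalence):
    """Delta-method Var for the nonanginal PPV: ~0.00440 (half-width 0.130)."""
    res = pv_covariance(cad_accuracy, cad_prevalence, "nonanginal", "ppv")
    assert res.cov[0, 0] == pytest.approx(0.00440, abs=5e-5)
    assert 1.96 * np.sqrt(res.cov[0, 0]) == pytest.approx(0.130, abs=1e-3)


@pytest.mark.parametrize("key,methods", TABLE5_INTERVALS.items())
def test_cad_interval_reproduction(cad_accuracy, cad_prevalence, key, methods):
    """All four interval variants reproduce the printed CAD table.

    Normal-approximation rows to +-0.001 per endpoint; t rows to +-0.002
    (their degrees of freedom are reconstructed, not printed).
    """
    group, side = key
    res = pv_covariance(cad_accuracy, cad_prevalence, group, side)
    for method, (lo, up) in methods.items():
        ci = confidence_interval(res, method=method)
        tol = 0.002 if method.endswith("-t") else 0.001
        assert ci.lower[0] == pytest.approx(lo, abs=tol), (group, side, method)
        assert ci.upper[0] == pytest.approx(up, abs=tol), (group, side, method)
        assert not ci.failed[0]


def test_additive_intervals_not_clipped():
    """Wald intervals may exceed [0, 1]; the logistic variant never does."""
    acc = facpv.summary_accuracy(0.95, 0.95, 20, 20)
    prev = facpv.read_prevalence([("g", 9, 10)])
    res = pv_covariance(acc, prev, "g", "ppv")
    add = confidence_interval(res, "additive-normal")
    log = confidence_interval(res, "logistic-normal")
    assert add.upper[0] > 1.0
    assert 0.0 < log.lower[0] < log.upper[0] < 1.0


def test_boundary_estimate_fails_logistic_and_t():
    """p_hat = 1 (all-positive toy table): logistic and t variants fail."""
    table = facpv.TestResultsTable(
        subject_id=list("abcdef"),
        gold=[1, 1, 1, 0, 0, 0],
        results=[[1], [1], [1], [0], [0], [0]],
    )
    with pytest.warns(UserWarning):
        acc = facpv.estimate_accuracy(table)
    prev = facpv.read_prevalence([("g", 1, 2)])
    res = pv_covariance(acc, prev, "g", "ppv")
    assert res.estimates[0] == 1.0
    for method in ("logistic-normal", "logistic-t", "additive-t"):
        ci = confidence_interval(res, method)
        assert ci.failed[0]
        assert np.isnan(ci.lower[0])
    add = confidence_interval(res, "additive-normal")
    assert not add.failed[0]


def test_fixed_prevalence_drops_variance_component(cad_accuracy):
    """With a known prevalence the pi component vanishes and the mercaldo
    variant coincides with the plain additive interval."""
    prev = facpv.read_prevalence([("fixed", 0.16, True)])
    res = pv_covariance(cad_accuracy, prev, "fixed", "ppv")
    assert np.all(res.components["pi"] == 0)
    a = confidence_interval(res, "additive-normal")
    m = confidence_interval(res, "mercaldo-additive")
    np.testing.assert_allclose(a.lower, m.lower)
    np.testing.assert_allclose(a.upper, m.upper)


def test_mercaldo_interval_strictly_shorter(cad_accuracy, cad_prevalence):
    """Ignoring prevalence uncertainty always shortens the interval."""
    for side in ("ppv", "npv"):
        for group in cad_prevalence.group_labels:
            res = pv_covariance(cad_accuracy, cad_prevalence, group, side)
            full = confidence_interval(res, "additive-normal")
            merc = confidence_interval(res, "mercaldo-additive")
            assert merc.length[0] < full.length[0]
            assert full.lower[0] < merc.lower[0] < merc.upper[0] < full.upper[0]


def test_duplicated_modalities_give_rank_one_covariance(cad_table, cad_prevalence):
    dup = facpv.TestResultsTable(
        subject_id=cad_table.subject_id,
        gold=cad_table.gold,
        results=np.repeat(cad_table.results, 2, axis=1),
    )
    acc = facpv.estimate_accuracy(dup)
    res = pv_covariance(acc, cad_prevalence, "nonanginal", "ppv")
    assert np.linalg.matrix_rank(res.cov, tol=1e-12) == 1
    lo, up = difference_interval(res, 0, 1)
    assert lo == pytest.approx(0.0, abs=1e-12)
    assert up == pytest.approx(0.0, abs=1e-12)


def test_self_difference_is_degenerate(cad_accuracy, cad_prevalence):
    res = pv_covariance(cad_accuracy, cad_prevalence, "typical", "npv")
    lo, up = difference_interval(res, 0, 0)
    assert lo == up == 0.0


def test_satterthwaite_single_component_limit():
    """With one variance component the combined df is that component's df."""
    nu = _satterthwaite(0.004, 0.0, 0.0, 37.2, 120.0, 500.0)
    assert float(nu) == pytest.approx(37.2)
    # all components vanish -> undefined
    assert np.isnan(float(_satterthwaite(0.0, 0.0, 0.0, 10.0, 10.0, 10.0)))


def test_t_df_positive_and_finite(cad_accuracy, cad_prevalence):
    for group in cad_prevalence.group_labels:
        for side in ("ppv", "npv"):
            res = pv_covariance(cad_accuracy, cad_prevalence, group, side)
            nu = t_degrees_of_freedom(res)
            assert np.isfinite(nu) and nu > 0


def test_difference_interval_matches_bootstrap(rng):
    """Delta-method difference CI vs a 10,000-draw parametric bootstrap.

    Diseased/non-diseased cell counts are resampled as multinomials and the
    prevalence study as a binomial; the percentile interval should agree with
    the Wald interval up to Monte-Carlo and skewness error.
    """
    n1 = n0 = 500
    m_g = 1000
    trial = facpv.generate_trial(
        se=[0.85, 0.80], sp=[0.90, 0.85], rho=0.4, n1=n1, n0=n0, seed=rng
    )
    prev_study = facpv.generate_prevalence_study(0.3, m_g, seed=rng)
    acc = facpv.estimate_accuracy(trial)
    res = pv_covariance(acc, prev_study, 0, "ppv")
    lo, up = difference_interval(res, 0, 1, method="additive-normal")

    B = 10_000
    x1 = trial.results[trial.gold == 1]
    x0 = trial.results[trial.gold == 0]

    def resample(block, n):
        cells = block[:, 0] * 2 + block[:, 1]  # joint cell index 0..3
        probs = np.bincount(cells, minlength=4) / n
        draws = rng.multinomial(n, probs, size=B)  # (B, 4)
        pos1 = (draws[:, 2] + draws[:, 3]) / n  # first modality positive
        pos2 = (draws[:, 1] + draws[:, 3]) / n
        return pos1, pos2

    se1, se2 = resample(x1, n1)
    fp1, fp2 = resample(x0, n0)
    pi_b = rng.binomial(m_g, prev_study.pi_hat[0], B) / m_g
    from facpv.predictive import _ppv

    diff = _ppv(se1, 1 - fp1, pi_b) - _ppv(se2, 1 - fp2, pi_b)
    blo, bup = np.quantile(diff, [0.025, 0.975])
    sd = float(np.std(diff))
    # quantile MC error plus the O(1/sqrt(n)) skewness gap between the
    # percentile and Wald constructions: a quarter bootstrap SD covers both
    tol = 0.25 * sd + 3 * sd / np.sqrt(B)
    assert lo == pytest.approx(blo, abs=tol)
    assert up == pytest.approx(bup, abs=tol)
    # and the two interval centers coincide up to resampling noise
    assert (lo + up) / 2 == pytest.approx((blo + bup) / 2, abs=0.1 * sd + 6 * sd / np.sqrt(B))
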