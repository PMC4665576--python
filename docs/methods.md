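# Methods

## Model and estimands

A factorial diagnostic trial examines every subject with M binary tests
(modalities; in multi-reader studies a "modality" is one reader × method
cell, flattened at read time).  Within the diseased (i = 1, n₁ subjects) and
non-diseased (i = 0, n₀ subjects) groups, the per-subject result vectors are
i.i.d. multivariate Bernoulli with success-probability vectors se (diseased)
and 1 − sp (non-diseased).  The gold standard is treated as error-free, and
complete cases are required: a missing outcome changes the covariance
structure of the estimators, so it is rejected rather than imputed.

Risk-group prevalences π_g are estimated in *prior* studies as π̂_g = k_g/m_g
(or supplied as fixed known constants).  Sensitivity and specificity are
assumed homogeneous across risk groups, so predictive values for group g
follow from Bayes' theorem,

    p₊ = se·π / (se·π + (1−sp)(1−π)),
    p₋ = sp·(1−π) / (sp·(1−π) + (1−se)·π),

evaluated at the plug-in estimates.  Valid inputs lie strictly inside (0, 1);
boundary prevalence counts (k ∈ {0, m}) are rejected because the asymptotics
require an open-interval parameter.

## Covariance of the estimators

All covariances in the package are finite-sample, i.e. Cov of the estimator
itself.  The root-N-normalised asymptotic covariance of the central limit
theorem equals N times these matrices; the substitution cancels everywhere
(intervals, test statistic, degrees of freedom), so N never appears in the
API.

From subject-level data,

    Cov(ŝe_l, ŝe_r) = (P̂_lr − ŝe_l ŝe_r)/n₁,

with P̂_lr the proportion of diseased subjects positive on both modalities
(the maximum-likelihood plug-in with denominator n₁, not n₁ − 1 — this is the
convention that reproduces the worked-example intervals); analogously for
specificity from joint negatives among the non-diseased.  The two groups are
independent, and the prevalence study is independent of both, with
Var(π̂_g) = π̂_g(1 − π̂_g)/m_g.

The multivariate delta method then gives, for side ± and modalities l, r,

    Cov(p̂_l, p̂_r) = ∂f/∂se|_l ∂f/∂se|_r Cov(ŝe_l, ŝe_r)
                   + ∂f/∂sp|_l ∂f/∂sp|_r Cov(ŝp_l, ŝp_r)
                   + ∂f/∂π|_l ∂f/∂π|_r Var(π̂_g),

the prevalence being shared across modalities (fully correlated between
them).  The gradients are analytic; for PPV with A = se·π,
B = (1−sp)(1−π), S = A + B:

    ∂p₊/∂se = πB/S²,  ∂p₊/∂sp = A(1−π)/S²,  ∂p₊/∂π = (se·B + A(1−sp))/S²,

and NPV by the symmetry se↔sp, π↔1−π.  The three additive terms are kept
separate in `PVResult.components`; they feed the fixed-prevalence variants
and the t degrees of freedom.

When only marginal summaries (se, sp, n₁, n₀) are available, the diagonal
binomial variances can still be formed, but cross-modality covariances
cannot; they are stored as NaN and any operation that needs them
(ANOVA-type test, multi-modality contrasts) refuses with an explanatory
error rather than silently assuming independence.

## Confidence intervals

Six variants, all two-sided at level 1 − α (default α = 0.05):

| method            | scale    | quantile | prevalence variance |
|-------------------|----------|----------|---------------------|
| additive-normal   | identity | z        | included            |
| additive-t        | identity | t_ν      | included            |
| logistic-normal   | logit    | z        | included            |
| logistic-t        | logit    | t_ν      | included            |
| mercaldo-additive | identity | z        | dropped             |
| mercaldo-logistic | logit    | z        | dropped             |

Additive intervals are p̂ ± q·sd(p̂) and are *not* clipped to [0, 1]: the
published lengths are reported unclipped, and clipping would distort the
length comparisons.  The logistic variants apply the delta method once more
on the logit scale, logit(p̂) ± q·sd(p̂)/(p̂(1−p̂)), and back-transform; they
are range-preserving by construction.  At boundary estimates p̂ ∈ {0, 1} the
logit transform and the t degrees of freedom are undefined: those variants
report `failed=True` (data, not an exception), the estimate is still
reported, and failure rates are tallied by the simulation engine.  The
"mercaldo" variants treat the prevalence as a known constant — the classical
fixed-π analysis — by zeroing its variance component.

### t degrees of freedom

The small-sample t calibration uses a Welch–Satterthwaite combination of the
three variance components c_x = (∂f/∂x)²·Var(x̂):

    ν = (c_se + c_sp + c_π)² / Σ_x c_x²/ν_x,

where each component's own df is moment-matched to its binomial variance
estimator: since Var[p̂(1−p̂)] ≈ (1−2p)²·p(1−p)/n by the delta method,
matching a scaled χ² gives

    ν_x = 2·n_x·p_x(1−p_x) / (1−2p_x)².

ν_x → ∞ as p̂_x → 1/2 (the variance estimator is then first-order exact) and
shrinks at extreme p̂_x, which is what makes the t correction matter exactly
where Wald intervals undercover.  A design alternative — assigning each
component the nominal df n_x − 1 — was evaluated and rejected: it yields
ν in the hundreds for the worked example, t intervals indistinguishable
from the normal ones, and simulated t coverage ≈ 0.938 instead of the
≈ 0.949 the moment-matched version attains; the moment-matched form also
reproduces the worked-example t intervals to within 0.001.  Because ν_x is
not bounded below by n_x − 1, ν itself can fall well below min(n₁, n₀, m_g)
(e.g. ν ≈ 47 in the nonanginal PPV cell with n₀ = 127).

Fixed prevalence contributes c_π = 0 and no df term.  For contrasts spanning
several modalities the per-source df are combined conservatively with the
minimum over the involved modalities (the single-modality derivation does not
extend uniquely).  The logistic-t interval reuses the same ν as the additive
t (ν is invariant under a common rescaling of the components, and the logit
transform rescales all three equally).

## Hypothesis testing

Equality of the M predictive values of one risk group and side,
H₀: T p = 0 with the centering matrix T = I − (1/M)𝟙𝟙', is tested with the
ANOVA-type statistic

    ATS = p̂'Tp̂ / tr(TC),    f̂ = [tr(TC)]² / tr[(TC)²],

referred to χ²_f̂/f̂ (Box approximation).  For M = 2 the contrast has rank 1,
so f̂ = 1 exactly and the ATS is the squared standardized difference.  On the
logit scale the same construction is applied to logit(p̂) with covariance
DCD, D = diag(1/(p̂(1−p̂))).  User-supplied contrast matrices are
symmetrised and verified idempotent.  Hypotheses are formulated within one
risk group at a time; p-values are not multiplicity-adjusted across groups or
sides — callers combining many tests should adjust externally.  tr(TC) = 0
(e.g. literally duplicated modalities) makes the statistic undefined and
raises.

## Synthetic data

`generate_trial` draws correlated binary outcomes by Gaussian-copula
thresholding: latent normals with a pairwise-calibrated correlation matrix
are dichotomised at the marginal quantiles.  The latent correlation for each
pair is solved numerically (Brent) so that the bivariate-normal orthant
probability reproduces the requested *binary* correlation ρ exactly;
requests outside the Fréchet bounds for the given margins raise with the
admissible range.  With heterogeneous margins the pairwise-calibrated matrix
can in principle lose positive definiteness; eigenvalues are then clipped and
the matrix renormalised.  `generate_prevalence_study` draws k ~ Bin(m, π)
and redraws boundary outcomes (counted in `meta['boundary_resamples']`),
since a boundary prevalence is outside the model's parameter space.

What the generators deliberately do not emulate: covariate-dependent
accuracy (se/sp varying with patient characteristics, e.g. BMI), imperfect
gold standards, missing outcomes, and clustered readers.  Tests passing on
these generators therefore validate the estimators under the stated i.i.d.
multivariate-Bernoulli model, not robustness to those violations.

## The coverage study

The engine crosses π ∈ {0.05, 0.25, 0.5}, se, sp ∈ {0.5, 0.75, 0.85, 0.9},
n₀ = n₁ ∈ {50, 100, 500} and m_g ∈ {100, 500, 1000} — n and m_g fully
crossed, 432 cells — with 10,000 replicates per cell by default.  Each
replicate draws ŝe ~ Bin(n₁, se)/n₁, ŝp ~ Bin(n₀, sp)/n₀,
π̂ ~ Bin(m_g, π)/m_g, computes the plug-in estimate and variance (gradients
evaluated at the estimates), builds all six intervals from the *same* draws
(the point estimator is identical across methods), and scores whether the
true p± at the design parameters is covered.  The fixed-π variants use the
same π̂ but a variance without the prevalence term — the misuse scenario in
which a known-prevalence method is applied to an estimated prevalence.

Conventions the published numbers leave open, fixed here as follows:

* replicates whose interval is undefined (boundary p̂) are excluded from that
  method's coverage and length denominators and counted in the failure rate —
  a non-existent interval can neither cover nor miss;
* a replicate where the plug-in estimate itself is 0/0 (possible only when
  both numerator and denominator vanish; probability ≪ 10⁻⁴ in the design)
  counts as a failure for every method;
* summary rows hold one parameter fixed and average the per-cell values of
  the remaining cells with equal weight; "Overall" averages all 432 cells.

Reproducibility: each cell receives a child seed spawned from the design
seed in the deterministic cell order, so results are independent of any
parallel scheduling.  The full design at 10,000 replicates runs in well
under a minute on one CPU (vectorised over replicates); the test suite
exercises the same design both at 10,000 and at a scaled-down 1,000
replicates per cell.

## Numerical notes and limitations

* Degenerate variance entries arising from exact duplication are clamped at
  −10⁻¹⁵ before the square root (floating-point noise around zero).
* The worked example in the README reports values computed by this package;
  the source study's own report quotes a whole-sample PPV of 0.83 and NPV of
  0.91, which the published 2×2 table contradicts (it yields 140/153 ≈ 0.915
  and 114/138 ≈ 0.826) — the two figures appear transposed there.  The
  package takes the table as input and does not attempt to reconcile the
  prose.
* Out of scope: ROC/AUC analysis, combining sequential tests into a global
  se/sp, covariate models for accuracy, joint testing across risk groups,
  and multiplicity adjustment.
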