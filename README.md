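# facpv

Risk-group-specific predictive values, confidence intervals and hypothesis
tests for factorial (multi-modality, multi-reader) diagnostic trials.

## The problem

A diagnostic trial reports how well a test separates diseased from
non-diseased subjects — its sensitivity (se) and specificity (sp).  What a
clinician needs, however, is the probability that a *patient* with a given
test result actually has (or does not have) the disease: the positive and
negative predictive values.  Bayes' theorem connects the two through the
pre-test probability of disease π:

    PPV = se·π / (se·π + (1−sp)(1−π))
    NPV = sp·(1−π) / (sp·(1−π) + (1−se)·π)

Because π varies strongly between risk groups, `facpv` computes predictive
values *per risk group*, using prevalence estimates π̂_g = k_g/m_g from prior
studies.  Crucially, those prevalence estimates carry sampling noise of their
own; treating them as known constants systematically understates the
uncertainty of the predictive values (interval coverage can drop below 80%
when nominal coverage is 95%).  `facpv` propagates all three error sources —
ŝe, ŝp and π̂ — through the multivariate delta method:

    Cov(p̂_l, p̂_r) = g_l' D_lr g_r,

with g_m the gradient of the Bayes transformation for modality m and D_lr the
joint covariance of (ŝe, ŝp, π̂).  When several diagnostic modalities (or
reader × method combinations) are applied to the same subjects, the
estimators are correlated; the full multivariate-Bernoulli covariance is
estimated from subject-level data, which enables

* **confidence intervals** per modality — additive (Wald) or logistic
  (logit-scale, range-preserving), each with a normal or a small-sample t
  quantile (Satterthwaite-type degrees of freedom), plus the fixed-prevalence
  ("mercaldo") variants for comparison;
* **the ANOVA-type statistic (ATS)** for H₀: all modalities have the same
  predictive value in a risk group, referred to a scaled χ²_f̂/f̂ with
  estimated degrees of freedom, and Wald intervals for arbitrary contrasts;
* **a coverage simulation engine** that reproduces the interval
  coverage/length/failure study over the full crossed design
  (π, se, sp) × n × m_g;
* **synthetic data generators** for correlated binary trials
  (Gaussian-copula thresholding, calibrated to a target binary correlation)
  and prevalence studies.

## Worked example: CT angiography for coronary artery disease

291 patients underwent multidetector CT angiography (MDCTA) with conventional
coronary angiography as gold standard; the 2×2 table is TP=140, FP=13,
FN=24, TN=114, so ŝe = 140/164 = 0.854 and ŝp = 114/127 = 0.898.  Pre-test
probabilities of disease by presenting symptom come from prior studies:
146/913 (nonanginal chest pain), 963/1,931 (atypical angina), 1,874/2,108
(typical angina).  The bundled fixture encodes exactly these data:

```sh
facpv pv examples/cad/cad_trial.csv \
    --prev "nonanginal:146/913" \
    --prev "atypical:963/1931" \
    --prev "typical:1874/2108"
```

prints (4 significant digits):

```
[nonanginal] PPV: 0.6135
    additive-normal: [0.4835, 0.7435]
    additive-t: [0.4801, 0.7469]
    logistic-normal: [0.4785, 0.7331]
    logistic-t: [0.4749, 0.7359]
[nonanginal] NPV: 0.9699
    additive-normal: [0.9578, 0.982]
    ...
[typical] PPV: 0.9852
    additive-normal: [0.9775, 0.993]
    ...
[typical] NPV: 0.4337
    additive-normal: [0.3359, 0.5315]
    ...
```

Reading: for a patient with nonanginal chest pain a *negative* MDCTA
virtually rules the disease out (NPV 0.97), while a *positive* result is
ambiguous (PPV 0.61 with a wide interval); for typical angina the roles
reverse (PPV 0.99, NPV 0.43).  The same analysis from Python:

```python
import facpv

table = facpv.TestResultsTable.from_counts(tp=140, fp=13, fn=24, tn=114)
acc = facpv.estimate_accuracy(table)
prev = facpv.read_prevalence([("nonanginal", 146, 913)])
res = facpv.pv_covariance(acc, prev, "nonanginal", side="ppv")
ci = facpv.confidence_interval(res, "logistic-normal")
print(res.estimates[0], ci.lower[0], ci.upper[0])
# 0.6134969325153374 0.4784610703628141 0.7330965200967807
```

With subject-level data for two or more modalities, `--test` (or
`facpv.ats_test`) compares the modalities' predictive values; with
summary-level input (`--se/--sp/--n1/--n0`) the cross-modality covariance is
unknown and the test is refused, but per-modality intervals remain available.

## The coverage study

`facpv simulate` (or `facpv.run_coverage_study`) crosses
π ∈ {0.05, 0.25, 0.5}, se, sp ∈ {0.5, 0.75, 0.85, 0.9}, n₀ = n₁ ∈ {50, 100,
500} and m_g ∈ {100, 500, 1000} — 432 cells, 10,000 replicates each by
default — drawing binomial estimates of se, sp and π per replicate, building
all six interval variants from the same draws and scoring coverage, length
and failure (boundary estimates where the logistic and t constructions are
undefined).  The fixed-prevalence variants use the same π̂ draw but omit its
variance, quantifying how badly the known-π assumption undercovers when the
prevalence is in fact estimated.

```sh
facpv simulate examples/sim_small.yaml --seed 1 --out scratch/sim   # quick smoke
facpv simulate --reps 10000 --seed 1 --out scratch/sim_full          # full design
```

## Layout

- `src/facpv/datatypes.py` — domain types (trial table, accuracy summary,
  prevalence spec, PV results, intervals, test results)
- `src/facpv/io.py` — CSV readers/writers, prevalence parsing
- `src/facpv/accuracy.py` — se/sp estimation with joint covariance
- `src/facpv/predictive.py` — Bayes transformation, delta-method covariance,
  interval variants, t degrees of freedom
- `src/facpv/inference.py` — ANOVA-type test, contrast intervals
- `src/facpv/synthetic.py` — correlated-trial and prevalence generators
- `src/facpv/simulation.py` — the coverage study engine
- `src/facpv/cli.py` — the `facpv` command
- `docs/methods.md` — statistical methods, conventions and limitations
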