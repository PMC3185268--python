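# Methods

This note documents the statistical machinery behind `triageiv`: the models
fitted, the synthetic data-generating process, the numerical conventions,
and the design decisions taken where more than one reasonable choice
existed.

## Notation

`Y` — binary outcome (1 = in-hospital death); `X` — binary treatment
(1 = ICU admission at first triage); `Z` — binary instrument; `W` — measured
baseline covariates; `U` — latent (unmeasured) confounder. Effects are
reported as odds ratios (OR) or risk differences (RD, admitted minus
refused).

## Estimators

**Crude / adjusted.** OR scale: logistic regression of `Y` on `X`
(plus `W` for the adjusted fit); Wald intervals from the inverse observed
information. RD scale: crude is the difference of arm event proportions
with a normal-approximation interval; adjusted is the `X` coefficient of an
OLS of `Y` on `X + W` (a linear probability model).

**Propensity-score arm.** The propensity score `e(W) = P(X=1|W)` is a
logistic fit. Matching is greedy 1:1 nearest-neighbour on `logit e(W)`,
without replacement, within a caliper of `0.2 × SD(logit e(W))` (sample SD,
n−1). The minority arm is matched into the majority arm — in a
high-admission-rate cohort the refused patients are the minority, which is
what makes nearly all of them matchable. Matched-cohort effects: logistic
`Y ~ X` over matched patients (OR) or difference of matched-arm
proportions (RD).

**Instrument diagnostics.** The first stage is an OLS of `X` (coded 0/1)
on `Z + W`. With a single instrument the partial F equals the squared
t statistic of `Z`'s coefficient and the partial r² equals
`t²/(t² + df_resid)`; both are pinned against brute-force nested-model
ANOVA and residual-correlation oracles in the tests. An instrument with
F < 10 is flagged weak. Candidate ranking is lexicographic: non-weak
first, then smallest mean |standardized difference| across covariates when
stratifying by the instrument, then largest partial F. The ranking had to
be made explicit because "strong and well balanced" does not by itself
order candidates that win on different criteria.

**Standardized differences.** Continuous:
`(m₁ − m₀)/√((s₁² + s₀²)/2)`; binary:
`(p₁ − p₀)/√((p₁(1−p₁) + p₀(1−p₀))/2)`; sign is group-1 minus group-0
(admitted minus refused). A zero pooled spread makes d undefined; such
covariates are reported as NaN and excluded from means.

**IV estimators.** Wald: ratio of instrument-stratum mean differences;
errors out when the instrument induces no treatment variation. 2SLS: OLS
`X ~ Z + W`, then OLS `Y ~ X̂ + W`. 2LR: the same chain with logistic
stages, reporting `exp(coef of X̂)`. Two-stage probit: probit stages, the
second-stage coefficient multiplied by 1.6 (the standard probit-to-logit
scale factor, exact only in the symmetric mid-range) before
exponentiation. 3LS: logistic `X ~ Z + W` produces `p̂`, which then plays
the role of the instrument in a 2SLS. With a single binary instrument and
no covariates, Wald, 2SLS and 3LS are algebraically identical (the
first-stage prediction spans the same two-valued space as `Z`); the test
suite enforces agreement to 1e-8.

The probit second stage receives the *response-scale* predicted
probability (not the linear index), paralleling the 2LR construction; this
was an open choice and is fixed here for comparability of the two
nonlinear chains.

**Bootstrap inference.** All IV intervals are nonparametric bootstrap
percentile intervals; second-stage analytic covariances are deliberately
discarded because the second stage conditions on an estimated regressor.
Resampling is by patient, or by whole cluster when a cluster column is
given (cluster labels are drawn with `integers` so that singleton clusters
reproduce patient-level resampling bit for bit). Replicates on which the
estimator raises (e.g. a zero Wald denominator) are dropped and counted;
inference is refused when more than 20% fail — beyond that the percentile
interval no longer describes the stated resampling distribution. The
two-sided p-value is `max(2·min(P(θ* ≤ θ₀), P(θ* ≥ θ₀)), 2/(B+1))` with
null θ₀ = 0 (RD) or 1 (OR); the floor keeps a finite bootstrap from
reporting p = 0.

## The synthetic cohort generator

Structural model per patient (all draws from one seeded generator, in a
fixed order, so cohorts are bit-reproducible):

```
W_j ~ Normal(loc_j, scale_j²) or Bernoulli(loc_j)
U   ~ Normal(0, σ_U²)
Z   ~ Bernoulli(π_Z)                        independent of (W, U)
P(X=1|Z,W,U) = expit(γ₀ + γ_Z Z + γ_W·W + γ_U U)
logistic outcome:       P(Y=1|X,W,U) = expit(α₀ + β_X X + α_W·W + α_U U)
linear-probability:     P(Y=1|X,W,U) = α₀ + β_X X + α_W·W + α_U U
```

`Z` never enters the outcome model or covariate generation, so the
exclusion restriction holds by construction. Under the linear-probability
outcome the true marginal RD is exactly `β_X`; this is what makes exact
recovery tests possible on the 2SLS/Wald scale. Linear-probability
configurations are rejected (not silently clamped) when more than 1% of
pre-clamp probabilities fall outside [0.01, 0.99]; within that band the
residual clamping is negligible. Under the logistic outcome `β_X` is a
conditional log OR and the marginal RD is obtained by Monte-Carlo
integration over `(W, U)` (`true_marginal_rd`).

**Default triage-like cohort** (`eldicus_default_config`): 8,201 patients,
five severity scores with means/SDs matching the admission-weighted
moments of a large European triage cohort — age 59.6 ± 18.3,
SOFA 4.84 ± 2.89, SAPS II 30.1 ± 15.7, GCS 12.5 ± 4.25,
Karnofsky 79.2 ± 20.0. Per-SD treatment log-odds effects
(age −0.40, SOFA +0.30, SAPS +0.35, GCS −0.65, Karnofsky −0.05) were set
so the arm-wise covariate mean differences have the direction and rough
magnitude seen in such cohorts; outcome effects (age +0.35, SOFA +0.35,
SAPS +0.40, GCS −0.30, Karnofsky −0.20) give a severity-driven mortality.
The binary instrument (prevalence 0.5, log-odds 0.8 ≈ admission OR 2.2)
emulates a physician-specialization practice pattern; the latent
confounder loads 0.6 on both models. Intercepts were calibrated once by
Monte-Carlo (5×10⁶ draws) to a marginal admission rate of 82.3% and
mortality of 25%, and are frozen in the source. The default true treatment
effect is **zero**, making the default cohort a null benchmark; pass
`treatment_effect=` for a real effect. A pure-noise binary column is added
for instrument-selection benchmarks, and seven uniform random clusters
exist solely to exercise cluster bootstrapping.

What the generator does *not* emulate: re-triage and repeated evaluations,
country-level structure in admission policy, missing data, measurement
error in severity scores, and effect modification. Passing recovery tests
therefore show estimator correctness under the stated structural model,
not robustness to those real-data features.

## Benchmark study designs (`benchmarks.py`)

* **Null recovery** — n = 10,000, linear-probability outcome, β_X = 0;
  one severity covariate with a strong triage effect (log-odds 3/SD) and a
  death effect of +0.14/SD; latent confounder with unit loadings on both
  models and σ_U = 0.08; instrument log-odds 1.5 (first-stage F ≈ 500).
  The crude OLS slope then carries a confounding bias of ≈ +0.19, which is
  also computed analytically as `cov(X, α_W·W + α_U U)/var(X)` from
  structural draws (no regression) and serves as the oracle. Under the
  linear-probability validity band a *latent* confounder alone cannot
  produce a large crude bias at unit loadings (its scale is capped at
  σ_U ≈ 0.19, and the bias is of order σ_U²), so the visible bias is
  carried by the measured covariate while the latent confounder is
  retained on top; 2SLS adjusts for the covariate and is consistent for 0.
* **Coverage** — n = 2,000, linear-probability, β_X = −0.05 exactly,
  strong instrument, mild latent confounding; 95% bootstrap percentile
  intervals (B = 200) for the Wald estimator, 200 replicate cohorts.
* **Weak instrument** — n = 5,000, ~82% admitted, instrument log-odds 0.4
  versus 0.2. At 0.2 the first-stage F sits near the weak threshold and
  the Wald denominator approaches its own sampling noise, so the empirical
  SD of the estimate more than doubles — the variance-inflation pathology
  that makes weak-IV intervals explode.
* **Balance study** — n = 2,000, three measured confounders, no latent
  part; used for matching-balance and instrument-ranking tests.

Replication counts (200 for mean-recovery and coverage, 50 for balance)
were chosen to keep Monte-Carlo error well inside the asserted tolerances
while the whole validation suite runs in about a minute.

## Numerical conventions and edge cases

* Regression engine delegates to statsmodels (OLS, Logit, Probit with
  Newton iterations, tol 1e-10); an intercept is always implicit and
  prepended, callers pass covariates only.
* Rank deficiency is detected by QR on the full design and reported with
  the names of the collinear columns; n < p is rejected.
* Separation in binary fits: statsmodels' own detection is translated to
  `SeparationError`, and any fit whose standardized slope magnitude
  (|coef| × SD of the column) exceeds 15 is likewise rejected — a
  logistic log-odds of 15 per SD has no finite-data support.
  Non-convergence is an error state, never a silent result.
* Propensity caliper floor: 1e-6 on the logit scale, so a degenerate
  (near-constant) propensity distribution still yields a usable caliper.
* Matching ties (equal distance) break on the smallest patient id;
  together with the seeded processing order this makes matching
  deterministic and platform-independent.
* Multi-stage RD estimates may legitimately fall outside [−1, 1]; they are
  flagged (`rd_outside_unit_interval`), never clipped.
* Bootstrap seeds, match seeds and simulation seeds are explicit
  everywhere; identical configuration + seeds reproduces every table
  byte for byte.

## Known limitations

* The IV estimand is a local average treatment effect (the compliers whose
  admission is shifted by the instrument), while matching estimates the
  effect on the treated; the two only coincide under homogeneous effects,
  as in the generator's constant-`β_X` models.
* The 2LR and two-stage probit chains are heuristic for dichotomous
  outcomes (plugging a predicted probability into a nonlinear second
  stage does not in general identify the structural OR); they are provided
  for method comparison, with the bootstrap quantifying their
  variability.
* The 1.6 probit-to-logit rescaling is an approximation that degrades for
  extreme probabilities; the suite only asserts 15% relative agreement on
  moderate effects.
* Greedy matching is order-dependent by construction (hence the seeded
  order and the exhaustive-order oracle in the tests); optimal matching is
  out of scope.
* Analysis-level covariances (e.g. between estimators compared on the same
  cohort) are not computed; estimators are compared descriptively, as in
  the motivating application.
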