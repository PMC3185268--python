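# triageiv

Causal estimation of the effect of ICU admission on in-hospital mortality
from observational triage cohorts — comparing standard regression,
propensity-score matching, and instrumental-variable (IV) methods for a
binary treatment and binary outcome.

## The problem

When critically ill patients are triaged for ICU admission, the admission
decision is driven by the same severity that drives death: sicker patients
are both more likely to be admitted (or, sometimes, refused as "too sick to
benefit") and more likely to die. A crude comparison of hospital mortality
between admitted and refused patients is therefore confounded, and even a
regression adjusted for all *measured* severity scores (age, SOFA, SAPS II,
GCS, Karnofsky) remains biased if prognostic factors are unmeasured at
triage time — which, in critical care, they almost certainly are.

Instrumental-variable analysis attacks the unmeasured part. An instrument
`Z` is a variable that (1) affects the outcome only through the treatment
(*exclusion restriction*), (2) strongly predicts the treatment, and (3) is
unrelated to patient characteristics. Practice-pattern variables — the
triaging physician's specialization or age, or the admission policy of the
country of enrolment — are natural candidates: they shift the admission
decision for reasons unrelated to the individual patient's prognosis.

## What the package computes

For a patient-level cohort (CSV, or the built-in synthetic generator):

* **Crude and adjusted regression** — logistic (odds-ratio scale) and
  linear/proportion-based (risk-difference scale) estimates with analytic
  Wald intervals.
* **Propensity-score arm** — logistic propensity model, greedy 1:1
  nearest-neighbour matching without replacement within a caliper of
  0.2 × SD of the logit propensity score, matched-cohort OR and RD, and
  standardized-difference balance tables before and after matching.
* **Instrument diagnostics and selection** — first-stage partial F
  statistic and partial r² (weak below F = 10), univariate odds ratio of
  instrument on treatment, covariate balance stratified by instrument
  versus by treatment, a country-rate dichotomizer (threshold 0.85), and a
  lexicographic ranking of candidates.
* **Five IV estimators** — the Wald ratio estimator
  `(E[Y|Z=1] − E[Y|Z=0]) / (E[X|Z=1] − E[X|Z=0])`, two-stage least squares
  (2SLS), two-stage logistic regression (2LR), a two-stage probit model
  (coefficients rescaled by 1.6 to the logit scale), and a three-stage
  least-squares variant (3LS) that uses a logistic first stage's predicted
  probability as the instrument in a 2SLS. All IV intervals come from a
  bootstrap (percentile method, patient- or cluster-level resampling);
  analytic second-stage standard errors are never reported because the
  second stage regresses on a generated regressor.
* **Synthetic cohorts with known truth** — a structural generator with a
  latent confounder loading on both triage and death, a binary instrument
  entering only the treatment model, and either a logistic outcome (true
  conditional log odds ratio) or a linear-probability outcome (true
  marginal risk difference, exactly).

## Worked example

Simulate the default triage-like cohort (8,201 patients, ~82% admitted,
~25% hospital mortality, latent confounding, **no true treatment effect**)
and run the full comparison:

```python
from triageiv import pipeline as pl
from triageiv import synthetic_data as sd

config = pl.AnalysisConfig(
    covariate_names=("age", "sofa", "saps", "gcs", "karnofsky"),
    instrument_candidates=("physician_specialty",),
    simulation=sd.eldicus_default_config(),
    bootstrap_iterations=1000,
    bootstrap_seed=42,
)
report = pl.run_full_analysis(config)
print(report.estimates_frame().to_string(index=False))
```

Output (abridged; 1,413 matched pairs, instrument `physician_specialty`):

```
 estimator scale  point  ci_low  ci_high  p_value    n            ci_method
     crude    OR  1.755   1.516    2.033    0.000 8201        wald_analytic
  adjusted    OR  1.422   1.217    1.662    0.000 8201        wald_analytic
ps_matched    OR  1.522   1.268    1.827    0.000 2826        wald_analytic
       2lr    OR  1.690   0.715    3.823    0.226 8201 bootstrap_percentile
   probit2    OR  1.637   0.725    3.612    0.232 8201 bootstrap_percentile
     crude    RD  0.096   0.074    0.119    0.000 8201        wald_analytic
  adjusted    RD  0.054   0.029    0.079    0.000 8201        wald_analytic
ps_matched    RD  0.069   0.039    0.099    0.000 2826        wald_analytic
      wald    RD  0.198   0.025    0.398    0.024 8201 bootstrap_percentile
      2sls    RD  0.161  -0.021    0.356    0.092 8201 bootstrap_percentile
       3ls    RD  0.026  -0.116    0.152    0.716 8201 bootstrap_percentile
```

Read it like this: the true effect in this simulation is null, but the
latent confounder makes admitted patients sicker, so the crude OR of 1.76
and RD of 0.10 are pure confounding. Adjustment and propensity matching
remove only the *measured* part (OR ≈ 1.4–1.5 — still biased). The IV
estimators, which exploit only the instrument-driven variation in
admission, give intervals that comfortably contain the null — at the price
of being several times wider than the regression intervals. Matching also
shrinks the mean absolute standardized difference of the severity scores
from ≈ 0.29 to ≈ 0.01.

The same analysis runs from the shell:

```bash
triageiv simulate --n 8201 --seed 1 --out cohort.csv
triageiv analyze --config analysis.yml --cohort cohort.csv --out report/
```

## Layout

```
src/triageiv/
  cohort.py          patient-level container (treatment/outcome/covariates)
  glm_core.py        OLS / logistic / probit fits with pinned contracts
  synthetic_data.py  structural cohort generator + default triage cohort
  benchmarks.py      fixed simulation-study designs used for validation
  propensity.py      propensity model, caliper matching, matched effects
  instruments.py     strength diagnostics, balance, candidate ranking
  iv_estimators.py   Wald, 2SLS, 2LR, two-stage probit, 3LS
  pipeline.py        crude/adjusted, bootstrap, full analysis, I/O
  cli.py             `triageiv simulate` / `triageiv analyze`
```

See `docs/methods.md` for the statistical details, default parameters and
known limitations.
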