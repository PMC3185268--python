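"""Synthetic triage cohorts with known causal structure.

The ELDICUS patient data are not publicly deposited, so the package ships a
generator that emulates a cohort of critically ill patients triaged for ICU
admission: continuous severity scores (age, SOFA, SAPS II, GCS, Karnofsky),
a binary instrument that shifts the admission decision but has no path to the
outcome (the exclusion restriction holds by construction), and a latent
standard-normal confounder ``U`` loading on both the admission decision and
hospital death.  Because the true treatment effect, confounder loadings and
instrument strength are all configurable, every downstream estimator can be
benchmarked against a known truth.

Structural model, per patient::

    W_j  ~ Normal(loc_j, scale_j^2)  or  Bernoulli(loc_j)      (covariates)
    U    ~ Normal(0, confounder_sd^2)                          (unmeasured)
    Z    ~ Bernoulli(instrument_prevalence), independent of (W, U)
    P(X=1 | Z, W, U) = expit(g0 + gz Z + sum_j gw_j W_j + gu U)
    logistic outcome:            P(Y=1 | X, W, U) = expit(a0 + bx X + aw.W + au U)
    linear-probability outcome:  P(Y=1 | X, W, U) = a0 + bx X + aw.W + au U

``Z`` never enters the outcome model and never enters covariate generation:
the instrument coefficient ``gz`` is the only path from ``Z`` into the system.
Under the linear-probability outcome the true marginal risk difference is
exactly ``bx``; under the logistic outcome ``bx`` is the true conditional
log odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, OUTCOME, PATIENT_ID, TREATMENT
from .errors import InvalidConfigError

LOGISTIC = "logistic"
LINEAR_PROBABILITY = "linear_probability"

#: linear-probability configs must keep pre-clamp event probabilities inside
#: this band for at least MIN_VALID_FRACTION of patients
PROB_BAND = (0.01, 0.99)
MIN_VALID_FRACTION = 0.99


@dataclass(frozen=True)
class CovariateSpec:
    name: str
    kind: str  # {"gaussian", "bernoulli"}
    location: float  # mean, or Bernoulli probability
    scale: float = 1.0  # SD; ignored for bernoulli

    def __post_init__(self):
        if self.kind not in ("gaussian", "bernoulli"):
            raise InvalidConfigError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "bernoulli" and not 0 <= self.location <= 1:
            raise InvalidConfigError(
                f"covariate {self.name!r}: bernoulli probability {self.location} not in [0,1]"
            )
        if self.kind == "gaussian" and self.scale < 0:
            raise InvalidConfigError(f"covariate {self.name!r}: negative scale")


@dataclass(frozen=True)
class TreatmentModel:
    """Log-odds model for the ICU admission decision."""

    intercept: float
    instrument_coef: float
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    confounder_coef: float = 0.0


@dataclass(frozen=True)
class OutcomeModel:
    """Hospital-mortality model; ``treatment_effect`` is a log odds ratio under
    the logistic kind and a risk difference under linear_probability."""

    intercept: float
    treatment_effect: float
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    confounder_coef: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    seed: int
    instrument_prevalence: float
    covariate_specs: tuple[CovariateSpec, ...]
    confounder_sd: float
    treatment_model: TreatmentModel
    outcome_model: OutcomeModel
    outcome_model_kind: str = LOGISTIC
    instrument_name: str = "instrument"
    cluster_count: int | None = None

    def __post_init__(self):
        if self.n_patients < 2:
            raise InvalidConfigError("n_patients must be at least 2")
        if not 0 <= self.instrument_prevalence <= 1:
            raise InvalidConfigError(
                f"instrument_prevalence {self.instrument_prevalence} not in [0,1]"
            )
        if self.confounder_sd < 0:
            raise InvalidConfigError("confounder_sd must be non-negative")
        if self.outcome_model_kind not in (LOGISTIC, LINEAR_PROBABILITY):
            raise InvalidConfigError(
                f"unknown outcome_model_kind {self.outcome_model_kind!r}"
            )
        if self.cluster_count is not None and self.cluster_count < 1:
            raise InvalidConfigError("cluster_count must be positive when given")
        names = [s.name for s in self.covariate_specs]
        if len(set(names)) != len(names):
            raise InvalidConfigError("covariate names are not unique")
        for model, label in (
            (self.treatment_model, "treatment_model"),
            (self.outcome_model, "outcome_model"),
        ):
            unknown = set(model.covariate_coefs) - set(names)
            if unknown:
                raise InvalidConfigError(
                    f"{label} references unknown covariates {sorted(unknown)}"
                )

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.covariate_specs)


def _linear_predictor(intercept, coefs, frame):
    lp = np.full(len(frame), float(intercept))
    for name, c in coefs.items():
        lp += c * frame[name].to_numpy(dtype=float)
    return lp


def simulate_cohort(config: SimulationConfig, return_latent: bool = False):
    """Draw one cohort from the structural model; bit-reproducible given seed.

    With ``return_latent=True`` also returns a frame holding the latent
    confounder and the noise-free treatment/outcome probabilities, for use as
    oracles in recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    cols: dict[str, np.ndarray] = {}
    for spec in config.covariate_specs:
        if spec.kind == "gaussian":
            cols[spec.name] = rng.normal(spec.location, spec.scale, size=n)
        else:
            cols[spec.name] = rng.binomial(1, spec.location, size=n).astype(float)
    frame = pd.DataFrame(cols, columns=list(config.covariate_names), index=range(n))

    u = rng.normal(0.0, config.confounder_sd, size=n)
    z = rng.binomial(1, config.instrument_prevalence, size=n)

    tm = config.treatment_model
    p_treat = expit(
        _linear_predictor(tm.intercept, tm.covariate_coefs, frame)
        + tm.instrument_coef * z
        + tm.confounder_coef * u
    )
    x = (rng.random(n) < p_treat).astype(int)

    om = config.outcome_model
    lp_out = (
        _linear_predictor(om.intercept, om.covariate_coefs, frame)
        + om.treatment_effect * x
        + om.confounder_coef * u
    )
    if config.outcome_model_kind == LOGISTIC:
        p_out = expit(lp_out)
    else:
        inside = (lp_out >= PROB_BAND[0]) & (lp_out <= PROB_BAND[1])
        if inside.mean() < MIN_VALID_FRACTION:
            raise InvalidConfigError(
                "outcome_model: linear-probability event probabilities fall "
                f"outside {PROB_BAND} for {(1 - inside.mean()) * 100:.1f}% of "
                f"patients (allowed: {(1 - MIN_VALID_FRACTION) * 100:.0f}%)"
            )
        p_out = np.clip(lp_out, 0.0, 1.0)
    y = (rng.random(n) < p_out).astype(int)

    frame.insert(0, PATIENT_ID, np.arange(n))
    frame[TREATMENT] = x
    frame[OUTCOME] = y
    frame[config.instrument_name] = z

    cluster_name = None
    if config.cluster_count is not None:
        cluster_name = "cluster_id"
        frame[cluster_name] = rng.integers(0, config.cluster_count, size=n)

    cohort = Cohort(
        data=frame,
        covariate_names=config.covariate_names,
        instrument_names=(config.instrument_name,),
        cluster_name=cluster_name,
    ).validate()

    if return_latent:
        latent = pd.DataFrame(
            {"u": u, "p_treatment": p_treat, "p_outcome": p_out}
        )
        return cohort, latent
    return cohort


def true_marginal_rd(config: SimulationConfig, mc_size: int = 200_000, seed: int = 0) -> float:
    """True marginal risk difference P(Y=1|do(X=1)) - P(Y=1|do(X=0)).

    Exact (``treatment_effect`` itself) for the linear-probability outcome;
    Monte-Carlo integration over (W, U) for the logistic outcome.
    """
    om = config.outcome_model
    if config.outcome_model_kind == LINEAR_PROBABILITY:
        return float(om.treatment_effect)
    rng = np.random.default_rng(seed)
    cols = {}
    for spec in config.covariate_specs:
        if spec.kind == "gaussian":
            cols[spec.name] = rng.normal(spec.location, spec.scale, size=mc_size)
        else:
            cols[spec.name] = rng.binomial(1, spec.location, size=mc_size).astype(float)
    frame = pd.DataFrame(cols, columns=list(config.covariate_names), index=range(mc_size))
    u = rng.normal(0.0, config.confounder_sd, size=mc_size)
    base = _linear_predictor(om.intercept, om.covariate_coefs, frame) + om.confounder_coef * u
    return float(np.mean(expit(base + om.treatment_effect) - expit(base)))


# ---------------------------------------------------------------------------
# Default ELDICUS-like configuration
# ---------------------------------------------------------------------------

#: severity-score moments of the emulated triage cohort (overall-cohort means
#: and SDs, admission-weighted across triage arms)
ELDICUS_COVARIATES = (
    CovariateSpec("age", "gaussian", 59.6, 18.3),
    CovariateSpec("sofa", "gaussian", 4.84, 2.89),
    CovariateSpec("saps", "gaussian", 30.1, 15.7),
    CovariateSpec("gcs", "gaussian", 12.5, 4.25),
    CovariateSpec("karnofsky", "gaussian", 79.2, 20.0),
)

# log-odds effects per SD of each score; raw coefficients divide by the SD
_TREAT_STD_COEFS = {
    "age": -0.40,
    "sofa": 0.30,
    "saps": 0.35,
    "gcs": -0.65,
    "karnofsky": -0.05,
}
_OUT_STD_COEFS = {
    "age": 0.35,
    "sofa": 0.35,
    "saps": 0.40,
    "gcs": -0.30,
    "karnofsky": -0.20,
}

# intercepts calibrated once by Monte-Carlo (5e6 draws) so that the marginal
# admission rate is ~0.823 and hospital mortality ~0.25
_ELDICUS_TREAT_INTERCEPT = 3.7413
_ELDICUS_OUT_INTERCEPT = -2.1131


def _raw_coefs(std_coefs, specs):
    out = {}
    for spec in specs:
        sd = spec.scale if spec.kind == "gaussian" else 1.0
        out[spec.name] = std_coefs[spec.name] / sd
    return out


def eldicus_default_config(
    n_patients: int = 8201,
    seed: int = 20110921,
    treatment_effect: float = 0.0,
    cluster_count: int | None = 7,
) -> SimulationConfig:
    """Default cohort emulating the triage study: ~8,200 patients, ~82.3%
    admitted, ~25% hospital mortality, a binary instrument of moderate
    strength (log-odds 0.8, i.e. admission OR ~2.2, emulating the treating
    physician's specialization), a pure-noise candidate column, and latent
    confounding of both triage and death.

    ``treatment_effect`` defaults to 0 (no causal effect of admission) so the
    default cohort doubles as a null benchmark; pass a nonzero log odds ratio
    to simulate a real effect.
    """
    specs = ELDICUS_COVARIATES
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        instrument_prevalence=0.5,
        covariate_specs=specs,
        confounder_sd=1.0,
        treatment_model=TreatmentModel(
            intercept=_ELDICUS_TREAT_INTERCEPT,
            instrument_coef=0.8,
            covariate_coefs=_raw_coefs(_TREAT_STD_COEFS, specs),
            confounder_coef=0.6,
        ),
        outcome_model=OutcomeModel(
            intercept=_ELDICUS_OUT_INTERCEPT,
            treatment_effect=treatment_effect,
            covariate_coefs=_raw_coefs(_OUT_STD_COEFS, specs),
            confounder_coef=0.6,
        ),
        outcome_model_kind=LOGISTIC,
        instrument_name="physician_specialty",
        cluster_count=cluster_count,
    )


def simulate_eldicus_cohort(config: SimulationConfig | None = None, noise_candidate: bool = True) -> Cohort:
    """Simulate the default cohort, optionally adding a pure-noise binary
    candidate instrument (``physician_age_high``) for selection benchmarks."""
    config = config or eldicus_default_config()
    cohort = simulate_cohort(config)
    if noise_candidate:
        rng = np.random.default_rng(config.seed + 1)
        cohort.data["physician_age_high"] = rng.binomial(1, 0.5, size=cohort.n)
        cohort = Cohort(
            data=cohort.data,
            covariate_names=cohort.covariate_names,
            instrument_names=cohort.instrument_names + ("physician_age_high",),
            cluster_name=cohort.cluster_name,
        )
    return cohort
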