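"""Instrumental-variable estimators of the effect of a binary treatment on a
binary outcome.

Five estimators are provided, differing in the regression family of each
stage and hence in the scale of the reported effect:

* ``wald_estimator`` — ratio of instrument-stratum differences,
  (E[Y|Z=1] - E[Y|Z=0]) / (E[X|Z=1] - E[X|Z=0]); risk-difference scale.
* ``two_stage_least_squares`` (2SLS) — OLS of treatment on instrument +
  covariates, then OLS of outcome on the first-stage prediction + the same
  covariates; risk-difference scale.
* ``two_stage_logistic`` (2LR) — both stages logistic; odds-ratio scale.
* ``two_stage_probit`` — both stages probit; the second-stage coefficient is
  multiplied by 1.6 (the usual probit-to-logit rescaling) and exponentiated
  to an approximate odds ratio.
* ``three_stage_ls`` (3LS) — a logistic model of treatment on instrument +
  covariates produces a predicted probability, which then serves as the
  instrument in a 2SLS; risk-difference scale.

Analytic second-stage standard errors are deliberately not reported: the
second stage regresses on a generated (estimated) regressor, so its nominal
covariance is wrong.  Confidence intervals and p-values for all IV estimators
come from the bootstrap (:func:`triageiv.pipeline.bootstrap_ci`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import glm_core
from .cohort import Cohort
from .errors import UninformativeInstrumentError
from .instruments import first_stage_strength, WEAK_F_THRESHOLD

PROBIT_TO_LOGIT = 1.6

OR_SCALE = "OR"
RD_SCALE = "RD"

#: flag attached when a multi-stage risk-difference estimate leaves [-1, 1]
IMPLAUSIBLE_RD = "rd_outside_unit_interval"
WEAK_INSTRUMENT = "weak_instrument"


@dataclass
class EffectEstimate:
    estimator: str
    scale: str  # {"OR", "RD"}
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    p_value: float | None = None
    n_used: int = 0
    ci_method: str = "none"  # {"none", "wald_analytic", "bootstrap_percentile"}
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.scale not in (OR_SCALE, RD_SCALE):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.ci_low is not None and self.ci_high is not None:
            if self.ci_low > self.ci_high:
                raise ValueError("ci_low exceeds ci_high")
        if self.scale == OR_SCALE and self.point <= 0:
            raise ValueError("odds ratios must be positive")
        if self.scale == RD_SCALE and not -1 <= self.point <= 1:
            # multi-stage estimates may leave the proportion-difference range;
            # they are flagged, never clipped
            if IMPLAUSIBLE_RD not in self.flags:
                self.flags = self.flags + (IMPLAUSIBLE_RD,)


def _stage_design(cohort: Cohort, lead: pd.Series, covariate_names) -> pd.DataFrame:
    covs = cohort.covariates(tuple(covariate_names)).astype(float)
    return pd.concat([lead.reset_index(drop=True), covs.reset_index(drop=True)], axis=1)


def _weak_flag(cohort: Cohort, z_name: str, covariate_names) -> tuple[str, ...]:
    strength = first_stage_strength(cohort, z_name, covariate_names)
    return (WEAK_INSTRUMENT,) if strength.partial_f < WEAK_F_THRESHOLD else ()


def wald_estimator(cohort: Cohort, z_name: str) -> EffectEstimate:
    """Classic IV ratio estimator for a binary instrument (risk-difference
    scale): difference of outcome means across instrument strata divided by
    the difference of treatment means."""
    z = cohort.column(z_name).astype(float)
    y = cohort.outcome
    x = cohort.treatment
    m1, m0 = z == 1, z == 0
    if not (m1.any() and m0.any()):
        raise UninformativeInstrumentError(f"instrument {z_name!r} has an empty stratum")
    denom = x[m1].mean() - x[m0].mean()
    if denom == 0:
        raise UninformativeInstrumentError(
            f"instrument {z_name!r} induces no variation in treatment"
        )
    num = y[m1].mean() - y[m0].mean()
    return EffectEstimate(
        estimator="wald", scale=RD_SCALE, point=float(num / denom), n_used=cohort.n
    )


def two_stage_least_squares(
    cohort: Cohort, z_name: str, covariate_names=()
) -> EffectEstimate:
    """2SLS: OLS first stage for treatment, OLS second stage of the outcome on
    the first-stage prediction plus the same covariates."""
    z = pd.Series(cohort.column(z_name).astype(float), name=z_name)
    stage1 = glm_core.fit_linear(_stage_design(cohort, z, covariate_names), cohort.treatment)
    xhat = pd.Series(stage1.fitted_values, name="xhat")
    if np.ptp(xhat.to_numpy()) < 1e-12:
        raise UninformativeInstrumentError("first-stage prediction is constant")
    stage2 = glm_core.fit_linear(_stage_design(cohort, xhat, covariate_names), cohort.outcome)
    # stage 1 IS the first-stage strength regression: partial F = t(Z)^2
    t = stage1.coef(z_name) / stage1.se(z_name)
    flags = (WEAK_INSTRUMENT,) if t * t < WEAK_F_THRESHOLD else ()
    return EffectEstimate(
        estimator="2sls", scale=RD_SCALE,
        point=stage2.coef("xhat"), n_used=cohort.n, flags=flags,
    )


def two_stage_logistic(
    cohort: Cohort, z_name: str, covariate_names=()
) -> EffectEstimate:
    """2LR: both stages logistic; the exponentiated second-stage coefficient
    of the predicted admission probability is reported as an odds ratio."""
    z = pd.Series(cohort.column(z_name).astype(float), name=z_name)
    stage1 = glm_core.fit_logistic(_stage_design(cohort, z, covariate_names), cohort.treatment)
    xhat = pd.Series(stage1.fitted_values, name="xhat")
    if np.ptp(xhat.to_numpy()) < 1e-12:
        raise UninformativeInstrumentError("first-stage prediction is constant")
    stage2 = glm_core.fit_logistic(_stage_design(cohort, xhat, covariate_names), cohort.outcome)
    return EffectEstimate(
        estimator="2lr", scale=OR_SCALE,
        point=float(np.exp(stage2.coef("xhat"))), n_used=cohort.n,
        flags=_weak_flag(cohort, z_name, covariate_names),
    )


def two_stage_probit(
    cohort: Cohort, z_name: str, covariate_names=()
) -> EffectEstimate:
    """Two-stage probit structural model; the second-stage probit coefficient
    is rescaled by 1.6 and exponentiated to an approximate odds ratio."""
    z = pd.Series(cohort.column(z_name).astype(float), name=z_name)
    stage1 = glm_core.fit_probit(_stage_design(cohort, z, covariate_names), cohort.treatment)
    xhat = pd.Series(stage1.fitted_values, name="xhat")
    if np.ptp(xhat.to_numpy()) < 1e-12:
        raise UninformativeInstrumentError("first-stage prediction is constant")
    stage2 = glm_core.fit_probit(_stage_design(cohort, xhat, covariate_names), cohort.outcome)
    return EffectEstimate(
        estimator="probit2", scale=OR_SCALE,
        point=float(np.exp(PROBIT_TO_LOGIT * stage2.coef("xhat"))), n_used=cohort.n,
        flags=_weak_flag(cohort, z_name, covariate_names),
    )


def three_stage_ls(
    cohort: Cohort, z_name: str, covariate_names=()
) -> EffectEstimate:
    """3LS: a logistic model of treatment on instrument + covariates yields a
    predicted probability, which is then used as the instrument in a 2SLS."""
    z = pd.Series(cohort.column(z_name).astype(float), name=z_name)
    stage0 = glm_core.fit_logistic(_stage_design(cohort, z, covariate_names), cohort.treatment)
    phat = stage0.fitted_values
    if np.ptp(phat) < 1e-12:
        raise UninformativeInstrumentError("stage-0 predicted probability is constant")
    derived = "_phat_instrument"
    aug = cohort.data.copy()
    aug[derived] = phat
    aug_cohort = replace(cohort, data=aug)
    est = two_stage_least_squares(aug_cohort, derived, covariate_names)
    weak = _weak_flag(cohort, z_name, covariate_names)
    return EffectEstimate(
        estimator="3ls", scale=RD_SCALE, point=est.point, n_used=cohort.n, flags=weak
    )


#: registry used by the pipeline and CLI
ESTIMATORS = {
    "wald": (wald_estimator, RD_SCALE),
    "2sls": (two_stage_least_squares, RD_SCALE),
    "2lr": (two_stage_logistic, OR_SCALE),
    "probit2": (two_stage_probit, OR_SCALE),
    "3ls": (three_stage_ls, RD_SCALE),
}
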