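"""Propensity-score estimation, caliper matching and matched-cohort effects.

The propensity score is the probability of ICU admission given the measured
baseline covariates, estimated by logistic regression.  Admitted and refused
patients are then paired 1:1 without replacement by greedy nearest-neighbour
matching on the logit of the score, within a caliper of 0.2 times the sample
SD of the logit score.  Effects on the matched cohort are reported as an odds
ratio (logistic fit of outcome on treatment) or a risk difference (difference
of matched-arm event proportions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glm_core, instruments
from .cohort import Cohort
from .errors import DegenerateResponseError, TriageIVError
from .iv_estimators import EffectEstimate

CALIPER_MULTIPLIER = 0.2
MIN_CALIPER = 1e-6


@dataclass
class PropensityFit:
    model: glm_core.FitResult
    ps: np.ndarray
    logit_ps: np.ndarray
    caliper: float
    covariate_names: tuple[str, ...]


@dataclass
class MatchedCohort:
    pairs: list[tuple]  # (treated patient_id, control patient_id)
    caliper_used: float
    n_unmatched_treated: int
    n_unmatched_control: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list:
        return [pid for pair in self.pairs for pid in pair]


def caliper_from_logit_ps(
    logit_ps, multiplier: float = CALIPER_MULTIPLIER
) -> float:
    """Caliper width: ``multiplier`` times the sample SD (n-1) of the logit
    propensity score, floored at :data:`MIN_CALIPER`."""
    sd = float(np.std(np.asarray(logit_ps, dtype=float), ddof=1))
    return max(multiplier * sd, MIN_CALIPER)


def fit_propensity(
    cohort: Cohort,
    covariate_names=None,
    caliper_multiplier: float = CALIPER_MULTIPLIER,
) -> PropensityFit:
    """Logistic propensity model of treatment on the named covariates.

    The caliper is ``caliper_multiplier`` (default 0.2) times the sample SD
    (n-1 denominator) of the logit propensity score, floored at 1e-6 so a
    degenerate score distribution still yields a usable width.
    """
    names = tuple(covariate_names) if covariate_names is not None else cohort.covariate_names
    design = cohort.covariates(names).astype(float)
    fit = glm_core.fit_logistic(design, cohort.treatment)
    ps = np.clip(fit.fitted_values, 1e-12, 1 - 1e-12)
    logit_ps = np.log(ps / (1 - ps))
    caliper = caliper_from_logit_ps(logit_ps, caliper_multiplier)
    return PropensityFit(
        model=fit, ps=ps, logit_ps=logit_ps, caliper=caliper, covariate_names=names
    )


def match_without_replacement(
    fit: PropensityFit, cohort: Cohort, seed: int = 0
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour caliper matching without replacement.

    Patients of the minority arm are processed in a seeded random order; each
    is paired with the nearest not-yet-used majority-arm patient whose logit
    propensity score lies within the caliper.  Distance ties break on the
    smallest patient id, so runs are reproducible across platforms.
    """
    x = cohort.treatment.astype(int)
    ids = cohort.patient_id
    lps = fit.logit_ps
    if len(lps) != cohort.n:
        raise TriageIVError("propensity fit does not match cohort size")
    treated_idx = np.flatnonzero(x == 1)
    control_idx = np.flatnonzero(x == 0)
    if treated_idx.size == 0 or control_idx.size == 0:
        raise TriageIVError("both treatment arms must be non-empty for matching")

    if treated_idx.size <= control_idx.size:
        minority, majority, minority_is_treated = treated_idx, control_idx, True
    else:
        minority, majority, minority_is_treated = control_idx, treated_idx, False

    rng = np.random.default_rng(seed)
    order = rng.permutation(minority.size)

    maj_lps = lps[majority]
    maj_ids = ids[majority]
    available = np.ones(majority.size, dtype=bool)
    pairs: list[tuple] = []
    for k in order:
        i = minority[k]
        d = np.abs(maj_lps - lps[i])
        d = np.where(available, d, np.inf)
        best = d.min()
        if not np.isfinite(best) or best > fit.caliper:
            continue
        candidates = np.flatnonzero(d == best)
        j = candidates[np.argmin(maj_ids[candidates])]
        available[j] = False
        if minority_is_treated:
            pairs.append((ids[i], maj_ids[j]))
        else:
            pairs.append((maj_ids[j], ids[i]))

    n_matched = len(pairs)
    n_unmatched_treated = treated_idx.size - n_matched
    n_unmatched_control = control_idx.size - n_matched
    return MatchedCohort(
        pairs=pairs,
        caliper_used=fit.caliper,
        n_unmatched_treated=n_unmatched_treated,
        n_unmatched_control=n_unmatched_control,
    )


def matched_effect(
    cohort: Cohort, matched: MatchedCohort, scale: str = "OR", level: float = 0.95
) -> EffectEstimate:
    """Treatment-effect estimate on the matched cohort.

    ``scale="OR"``: logistic fit of outcome on treatment over the matched
    patients, exp(slope) with a Wald interval.  ``scale="RD"``: difference of
    matched-arm event proportions with a normal-approximation interval.
    """
    if matched.n_pairs < 2:
        raise TriageIVError("need at least 2 matched pairs")
    sub = cohort.subset_ids(matched.matched_ids())
    y, x = sub.outcome, sub.treatment
    if len(np.unique(y)) < 2:
        raise DegenerateResponseError("matched cohort has a single outcome value")
    zq = stats.norm.ppf(0.5 + level / 2)
    if scale == "OR":
        fit = glm_core.fit_logistic(x[:, None], y, names=("treatment",))
        slope, se = fit.coef("treatment"), fit.se("treatment")
        p = 2 * stats.norm.sf(abs(slope / se))
        return EffectEstimate(
            estimator="ps_matched", scale="OR",
            point=float(np.exp(slope)),
            ci_low=float(np.exp(slope - zq * se)),
            ci_high=float(np.exp(slope + zq * se)),
            level=level, p_value=float(p), n_used=sub.n,
            ci_method="wald_analytic",
        )
    if scale == "RD":
        p1, p0 = y[x == 1].mean(), y[x == 0].mean()
        n1, n0 = int((x == 1).sum()), int((x == 0).sum())
        se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
        rd = p1 - p0
        p = 2 * stats.norm.sf(abs(rd / se)) if se > 0 else float("nan")
        return EffectEstimate(
            estimator="ps_matched", scale="RD",
            point=float(rd),
            ci_low=float(rd - zq * se), ci_high=float(rd + zq * se),
            level=level, p_value=float(p), n_used=sub.n,
            ci_method="wald_analytic",
        )
    raise ValueError(f"unknown scale {scale!r}")


def balance_table(
    cohort: Cohort, covariate_names=None, matched: MatchedCohort | None = None
) -> pd.DataFrame:
    """Standardized differences by treatment arm, over the whole cohort or,
    when ``matched`` is given, over the matched subset only."""
    names = tuple(covariate_names) if covariate_names is not None else cohort.covariate_names
    sub = cohort if matched is None else cohort.subset_ids(matched.matched_ids())
    return instruments.balance_by(sub, sub.treatment, names)
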