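"""Candidate-instrument construction, strength diagnostics and selection.

A valid instrument must (1) affect the outcome only through treatment,
(2) strongly predict treatment, and (3) be unrelated to patient
characteristics.  Requirement (1) is untestable; this module quantifies (2)
via the first-stage partial F statistic and partial r² (treatment recoded
0/1 and regressed linearly on the instrument plus covariates) and the
univariate odds ratio of instrument on treatment, and (3) via standardized
differences of the covariates stratified by the instrument, compared with the
same differences stratified by the actual treatment.  A first-stage partial
F below 10 flags the instrument as weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, TREATMENT
from .errors import CohortError
from . import glm_core

WEAK_F_THRESHOLD = 10.0


# ---------------------------------------------------------------------------
# Standardized differences
# ---------------------------------------------------------------------------

def standardized_difference(group1, group0, kind: str | None = None) -> float:
    """Standardized difference between two groups of a covariate.

    Continuous: (m1 - m0) / sqrt((s1^2 + s0^2) / 2), sample SDs (n-1).
    Binary:     (p1 - p0) / sqrt((p1(1-p1) + p0(1-p0)) / 2).

    ``kind`` is inferred when omitted (binary iff all values are 0/1).
    Returns NaN when the pooled spread is zero (undefined d).
    """
    x1 = np.asarray(group1, dtype=float)
    x0 = np.asarray(group0, dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("each group needs at least 2 observations")
    if kind is None:
        both = np.concatenate([x1, x0])
        kind = "binary" if np.all(np.isin(both, (0.0, 1.0))) else "continuous"
    if kind == "binary":
        p1, p0 = x1.mean(), x0.mean()
        denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
        diff = p1 - p0
    elif kind == "continuous":
        v1, v0 = x1.var(ddof=1), x0.var(ddof=1)
        denom = np.sqrt((v1 + v0) / 2)
        diff = x1.mean() - x0.mean()
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if denom == 0:
        return float("nan")
    return float(diff / denom)


def balance_by(cohort: Cohort, strata: np.ndarray, covariate_names) -> pd.DataFrame:
    """Per-covariate standardized differences between strata 1 and 0.

    Sign convention: stratum-1 minus stratum-0 (admitted minus refused when
    stratifying by treatment).  Covariates with undefined d are reported as
    NaN and excluded from the mean absolute difference.
    """
    strata = np.asarray(strata)
    rows = {}
    for name in covariate_names:
        x = cohort.column(name).astype(float)
        rows[name] = standardized_difference(x[strata == 1], x[strata == 0])
    table = pd.DataFrame({"standardized_difference": pd.Series(rows)})
    table.index.name = "covariate"
    return table


def mean_abs_d(table: pd.DataFrame) -> float:
    d = table["standardized_difference"]
    return float(d.abs().mean(skipna=True))


# ---------------------------------------------------------------------------
# Strength diagnostics
# ---------------------------------------------------------------------------

@dataclass
class FirstStageStrength:
    coefficient: float  # linear effect of Z on X given covariates
    coefficient_se: float
    partial_f: float
    p_value: float
    partial_r2: float
    df_resid: int


def first_stage_strength(cohort: Cohort, z_name: str, covariate_names=()) -> FirstStageStrength:
    """Partial F and partial r² of the instrument in the first-stage OLS of
    treatment (0/1) on instrument plus covariates.

    With a single instrument the partial F equals the squared t statistic of
    its coefficient, and partial r² = t² / (t² + residual df).
    """
    design = pd.concat(
        [pd.Series(cohort.column(z_name).astype(float), name=z_name),
         cohort.covariates(tuple(covariate_names)).astype(float)],
        axis=1,
    )
    fit = glm_core.fit_linear(design, cohort.treatment)
    coef = fit.coef(z_name)
    se = fit.se(z_name)
    df_resid = fit.n_obs - len(fit.coefficient_names)
    t = coef / se
    partial_f = t * t
    p = float(stats.f.sf(partial_f, 1, df_resid))
    partial_r2 = partial_f / (partial_f + df_resid)
    return FirstStageStrength(
        coefficient=coef,
        coefficient_se=se,
        partial_f=float(partial_f),
        p_value=p,
        partial_r2=float(partial_r2),
        df_resid=df_resid,
    )


def instrument_treatment_or(cohort: Cohort, z_name: str, level: float = 0.95):
    """Univariate logistic odds ratio of treatment on the binary instrument,
    with a Wald confidence interval."""
    z = cohort.column(z_name).astype(float)
    if not np.all(np.isin(z, (0.0, 1.0))):
        raise CohortError(f"instrument {z_name!r} is not binary")
    if len(np.unique(z)) < 2:
        raise CohortError(f"instrument {z_name!r} has an empty stratum")
    fit = glm_core.fit_logistic(z[:, None], cohort.treatment, names=(z_name,))
    slope, se = fit.coef(z_name), fit.se(z_name)
    zq = stats.norm.ppf(0.5 + level / 2)
    return (
        float(np.exp(slope)),
        float(np.exp(slope - zq * se)),
        float(np.exp(slope + zq * se)),
    )


# ---------------------------------------------------------------------------
# Candidate construction
# ---------------------------------------------------------------------------

def group_admission_rates(cohort: Cohort, group_column: str) -> pd.Series:
    df = cohort.data
    if group_column not in df.columns:
        raise CohortError(f"column {group_column!r} not present in cohort")
    return df.groupby(group_column, observed=True)[TREATMENT].mean()


def dichotomize_by_group_rate(
    cohort: Cohort, group_column: str, threshold: float = 0.85
) -> pd.Series:
    """Binary candidate: 1 for patients in groups (e.g. countries) whose
    admission rate is at or above ``threshold``, 0 below.

    Emits a warning when the result is constant (degenerate candidate).
    """
    rates = group_admission_rates(cohort, group_column)
    if len(rates) < 2:
        warnings.warn(
            f"{group_column!r} has a single group; candidate is degenerate",
            stacklevel=2,
        )
    high = (rates >= threshold).astype(int)
    out = cohort.data[group_column].map(high).astype(int)
    out.name = f"{group_column}_high_rate"
    if out.nunique() < 2:
        warnings.warn(
            f"dichotomized candidate {out.name!r} is constant at threshold "
            f"{threshold}; degenerate instrument",
            stacklevel=2,
        )
    return out


def even_split_threshold(cohort: Cohort, group_column: str) -> float:
    """Group-rate cut point dividing the patients into two groups of the most
    nearly equal size (scanned over the observed per-group admission rates)."""
    rates = group_admission_rates(cohort, group_column)
    sizes = cohort.data[group_column].value_counts()
    order = rates.sort_values()
    best_thr, best_gap = float(order.iloc[0]), float("inf")
    n = cohort.n
    for thr in order.unique():
        n_high = int(sizes[order.index[order >= thr]].sum())
        gap = abs(2 * n_high - n)
        if gap < best_gap:
            best_gap, best_thr = gap, float(thr)
    return best_thr


# ---------------------------------------------------------------------------
# Evaluation and ranking
# ---------------------------------------------------------------------------

@dataclass
class InstrumentReport:
    name: str
    or_z_on_x: float
    or_ci: tuple[float, float]
    first_stage_coefficient: float
    first_stage_coefficient_sd: float
    partial_f: float
    partial_f_pvalue: float
    partial_r2: float
    balance_by_iv: pd.DataFrame
    balance_by_treatment: pd.DataFrame
    mean_abs_d_by_iv: float
    mean_abs_d_by_treatment: float
    weak: bool


def evaluate_instrument(cohort: Cohort, z_name: str, covariate_names) -> InstrumentReport:
    strength = first_stage_strength(cohort, z_name, covariate_names)
    oratio, lo, hi = instrument_treatment_or(cohort, z_name)
    by_iv = balance_by(cohort, cohort.column(z_name), covariate_names)
    by_x = balance_by(cohort, cohort.treatment, covariate_names)
    return InstrumentReport(
        name=z_name,
        or_z_on_x=oratio,
        or_ci=(lo, hi),
        first_stage_coefficient=strength.coefficient,
        first_stage_coefficient_sd=strength.coefficient_se,
        partial_f=strength.partial_f,
        partial_f_pvalue=strength.p_value,
        partial_r2=strength.partial_r2,
        balance_by_iv=by_iv,
        balance_by_treatment=by_x,
        mean_abs_d_by_iv=mean_abs_d(by_iv),
        mean_abs_d_by_treatment=mean_abs_d(by_x),
        weak=strength.partial_f < WEAK_F_THRESHOLD,
    )


def evaluate_candidates(
    cohort: Cohort, candidate_names, covariate_names
) -> list[InstrumentReport]:
    """Rank candidate instruments: non-weak (F >= 10) before weak, then by the
    smallest residual imbalance when stratifying by the instrument, then by
    the largest partial F."""
    if not candidate_names:
        raise ValueError("at least one candidate instrument is required")
    reports = [evaluate_instrument(cohort, z, covariate_names) for z in candidate_names]
    reports.sort(key=lambda r: (r.weak, r.mean_abs_d_by_iv, -r.partial_f))
    return reports


def reports_to_frame(reports: list[InstrumentReport]) -> pd.DataFrame:
    """Flatten instrument reports into one diagnostics row per candidate."""
    rows = []
    for r in reports:
        rows.append(
            {
                "instrument": r.name,
                "or_z_on_x": r.or_z_on_x,
                "or_ci_low": r.or_ci[0],
                "or_ci_high": r.or_ci[1],
                "partial_r2": r.partial_r2,
                "partial_f": r.partial_f,
                "p_value": r.partial_f_pvalue,
                "first_stage_coef": r.first_stage_coefficient,
                "first_stage_coef_sd": r.first_stage_coefficient_sd,
                "mean_abs_d_by_iv": r.mean_abs_d_by_iv,
                "mean_abs_d_by_treatment": r.mean_abs_d_by_treatment,
                "weak": r.weak,
            }
        )
    return pd.DataFrame(rows)
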