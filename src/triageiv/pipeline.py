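"""Orchestration: crude/adjusted regression, bootstrap inference, the full
comparative analysis, and cohort / report I/O.

The full analysis reproduces the comparative design of the study: covariate
balance before and after propensity matching, candidate-instrument
diagnostics and selection, crude and covariate-adjusted regression estimates,
the propensity-matched estimate, and the instrumental-variable estimators
with bootstrap percentile confidence intervals — each on both the odds-ratio
and the risk-difference scale where applicable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import glm_core, instruments, iv_estimators, propensity
from .cohort import Cohort, OUTCOME, PATIENT_ID, TREATMENT
from .errors import (
    BootstrapFailureError,
    CohortError,
    DegenerateResponseError,
    TriageIVError,
)
from .iv_estimators import EffectEstimate, OR_SCALE, RD_SCALE
from .synthetic_data import SimulationConfig, simulate_cohort


# ---------------------------------------------------------------------------
# Crude and adjusted estimates
# ---------------------------------------------------------------------------

def crude_and_adjusted(
    cohort: Cohort, covariate_names=None, scale: str = OR_SCALE, level: float = 0.95
) -> tuple[EffectEstimate, EffectEstimate]:
    """Unadjusted and covariate-adjusted regression estimates of the treatment
    effect.

    OR scale: logistic regressions of outcome on treatment (plus covariates
    for the adjusted fit), exp(slope) with Wald intervals.  RD scale: crude is
    the admitted-minus-refused difference of event proportions with a normal
    interval; adjusted is the treatment coefficient of an OLS of outcome on
    treatment plus covariates.
    """
    names = tuple(covariate_names) if covariate_names is not None else cohort.covariate_names
    y, x = cohort.outcome, cohort.treatment
    for arm in (0, 1):
        if len(np.unique(y[x == arm])) < 2:
            raise DegenerateResponseError(f"outcome is degenerate in arm {arm}")
    zq = stats.norm.ppf(0.5 + level / 2)

    def _wald(est_name, scale_, point, slope, se, transform):
        p = 2 * stats.norm.sf(abs(slope / se)) if se > 0 else float("nan")
        return EffectEstimate(
            estimator=est_name, scale=scale_, point=point,
            ci_low=transform(slope - zq * se), ci_high=transform(slope + zq * se),
            level=level, p_value=float(p), n_used=cohort.n,
            ci_method="wald_analytic",
        )

    xcol = pd.Series(x, name=TREATMENT)
    covs = cohort.covariates(names).astype(float).reset_index(drop=True)
    adj_design = pd.concat([xcol, covs], axis=1)

    if scale == OR_SCALE:
        crude_fit = glm_core.fit_logistic(x[:, None], y, names=(TREATMENT,))
        b, se = crude_fit.coef(TREATMENT), crude_fit.se(TREATMENT)
        crude = _wald("crude", OR_SCALE, float(np.exp(b)), b, se, lambda v: float(np.exp(v)))
        adj_fit = glm_core.fit_logistic(adj_design, y)
        b, se = adj_fit.coef(TREATMENT), adj_fit.se(TREATMENT)
        adjusted = _wald("adjusted", OR_SCALE, float(np.exp(b)), b, se, lambda v: float(np.exp(v)))
        return crude, adjusted
    if scale == RD_SCALE:
        p1, p0 = y[x == 1].mean(), y[x == 0].mean()
        n1, n0 = int((x == 1).sum()), int((x == 0).sum())
        se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
        crude = _wald("crude", RD_SCALE, float(p1 - p0), p1 - p0, se, float)
        adj_fit = glm_core.fit_linear(adj_design, y)
        b, se = adj_fit.coef(TREATMENT), adj_fit.se(TREATMENT)
        adjusted = _wald("adjusted", RD_SCALE, float(b), b, se, float)
        return crude, adjusted
    raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

MAX_FAILED_FRACTION = 0.2


def _resample_indices(rng, cohort: Cohort, cluster_name: str | None) -> np.ndarray:
    n = cohort.n
    if cluster_name is None:
        return rng.integers(0, n, size=n)
    clusters = cohort.column(cluster_name)
    labels = np.unique(clusters)
    # drawn via integers so that size-1 clusters reproduce patient resampling
    picked = labels[rng.integers(0, len(labels), size=len(labels))]
    groups = {lab: np.flatnonzero(clusters == lab) for lab in labels}
    return np.concatenate([groups[lab] for lab in picked])


def bootstrap_ci(
    estimator: Callable[[Cohort], EffectEstimate],
    cohort: Cohort,
    b_iterations: int = 1000,
    cluster_name: str | None = None,
    seed: int = 0,
    level: float = 0.95,
) -> EffectEstimate:
    """Nonparametric bootstrap percentile interval for any estimator.

    Units are patients, or whole clusters when ``cluster_name`` is given
    (cluster sampling).  Replicates on which the estimator raises a
    package-level error (e.g. a zero Wald denominator in a resample) are
    dropped and counted; inference is refused when more than 20% fail.
    The two-sided p-value is the proportion of replicates at or beyond the
    null (0 for risk differences, 1 for odds ratios), doubled and floored at
    2/(B+1).
    """
    if b_iterations < 1:
        raise ValueError("b_iterations must be at least 1")
    point_est = estimator(cohort)
    rng = np.random.default_rng(seed)
    reps = np.empty(b_iterations)
    n_failed = 0
    kept = 0
    for _ in range(b_iterations):
        idx = _resample_indices(rng, cohort, cluster_name)
        try:
            reps[kept] = estimator(cohort.take(idx)).point
            kept += 1
        except TriageIVError:
            n_failed += 1
    if n_failed > MAX_FAILED_FRACTION * b_iterations:
        raise BootstrapFailureError(
            f"{n_failed}/{b_iterations} bootstrap replicates failed "
            f"(> {MAX_FAILED_FRACTION:.0%}); interval not reported"
        )
    reps = reps[:kept]
    alpha = 1 - level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    null = 1.0 if point_est.scale == OR_SCALE else 0.0
    prop_le = float(np.mean(reps <= null))
    prop_ge = float(np.mean(reps >= null))
    p = max(2 * min(prop_le, prop_ge), 2 / (b_iterations + 1))
    flags = point_est.flags
    if n_failed:
        flags = flags + (f"bootstrap_failed_replicates={n_failed}",)
    return EffectEstimate(
        estimator=point_est.estimator, scale=point_est.scale,
        point=point_est.point,
        ci_low=float(lo),
        ci_high=float(hi),
        level=level, p_value=float(min(p, 1.0)), n_used=point_est.n_used,
        ci_method="bootstrap_percentile", flags=flags,
    )


# ---------------------------------------------------------------------------
# Analysis configuration and full run
# ---------------------------------------------------------------------------

DEFAULT_ESTIMATORS = ("wald", "2sls", "2lr", "probit2", "3ls")


@dataclass
class AnalysisConfig:
    covariate_names: tuple[str, ...]
    instrument_candidates: tuple[str, ...]
    cohort_path: str | None = None
    simulation: SimulationConfig | None = None
    treatment_name: str = TREATMENT
    outcome_name: str = OUTCOME
    cluster_name: str | None = None
    estimators: tuple[str, ...] = DEFAULT_ESTIMATORS
    bootstrap_iterations: int = 1000
    bootstrap_seed: int = 0
    match_seed: int = 0
    confidence_level: float = 0.95
    yes_no_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.bootstrap_iterations < 1:
            raise ValueError("bootstrap_iterations must be at least 1")
        if (self.cohort_path is None) == (self.simulation is None):
            raise ValueError("exactly one of cohort_path or simulation must be given")
        unknown = set(self.estimators) - set(iv_estimators.ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators {sorted(unknown)}")


@dataclass
class AnalysisReport:
    balance_pre: pd.DataFrame | None = None
    balance_post: pd.DataFrame | None = None
    instrument_table: pd.DataFrame | None = None
    selected_instrument: str | None = None
    or_estimates: list[EffectEstimate] = field(default_factory=list)
    rd_estimates: list[EffectEstimate] = field(default_factory=list)
    n_pairs: int | None = None
    errors: dict[str, str] = field(default_factory=dict)

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.or_estimates + self.rd_estimates:
            rows.append(
                {
                    "estimator": est.estimator,
                    "scale": est.scale,
                    "point": est.point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_value": est.p_value,
                    "n": est.n_used,
                    "ci_method": est.ci_method,
                    "flags": ";".join(est.flags),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["estimator", "scale", "point", "ci_low", "ci_high",
                     "p_value", "n", "ci_method", "flags"],
        )


def _load_cohort(config: AnalysisConfig) -> Cohort:
    if config.simulation is not None:
        return simulate_cohort(config.simulation)
    return read_cohort_csv(config.cohort_path, config)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the comparative analysis end to end.

    Stage order: balance table, propensity arm (fit, match, post-match
    balance, matched effects), instrument evaluation and selection, crude and
    adjusted estimates, IV estimators with bootstrap intervals.  A failing
    stage is recorded under its name and the partial report returned.
    """
    report = AnalysisReport()
    try:
        cohort = _load_cohort(config)
    except Exception as exc:  # noqa: BLE001 - surfaced with stage name
        report.errors["load_cohort"] = str(exc)
        return report
    covs = config.covariate_names

    try:
        report.balance_pre = propensity.balance_table(cohort, covs)
    except Exception as exc:
        report.errors["balance_pre"] = str(exc)

    matched = None
    try:
        ps_fit = propensity.fit_propensity(cohort, covs)
        matched = propensity.match_without_replacement(ps_fit, cohort, seed=config.match_seed)
        report.n_pairs = matched.n_pairs
        report.balance_post = propensity.balance_table(cohort, covs, matched=matched)
        report.or_estimates.append(
            propensity.matched_effect(cohort, matched, scale=OR_SCALE, level=config.confidence_level)
        )
        report.rd_estimates.append(
            propensity.matched_effect(cohort, matched, scale=RD_SCALE, level=config.confidence_level)
        )
    except Exception as exc:
        report.errors["propensity"] = str(exc)

    z_name = None
    try:
        reports = instruments.evaluate_candidates(cohort, config.instrument_candidates, covs)
        report.instrument_table = instruments.reports_to_frame(reports)
        z_name = reports[0].name
        report.selected_instrument = z_name
    except Exception as exc:
        report.errors["instruments"] = str(exc)

    try:
        c_or, a_or = crude_and_adjusted(cohort, covs, scale=OR_SCALE, level=config.confidence_level)
        c_rd, a_rd = crude_and_adjusted(cohort, covs, scale=RD_SCALE, level=config.confidence_level)
        report.or_estimates = [c_or, a_or] + report.or_estimates
        report.rd_estimates = [c_rd, a_rd] + report.rd_estimates
    except Exception as exc:
        report.errors["crude_and_adjusted"] = str(exc)

    if z_name is not None:
        for name in config.estimators:
            func, scale = iv_estimators.ESTIMATORS[name]
            if name == "wald":
                est_call = lambda c, f=func: f(c, z_name)  # noqa: E731
            else:
                est_call = lambda c, f=func: f(c, z_name, covs)  # noqa: E731
            try:
                est = bootstrap_ci(
                    est_call, cohort,
                    b_iterations=config.bootstrap_iterations,
                    cluster_name=config.cluster_name,
                    seed=config.bootstrap_seed,
                    level=config.confidence_level,
                )
            except Exception as exc:
                report.errors[f"iv:{name}"] = str(exc)
                continue
            (report.or_estimates if scale == OR_SCALE else report.rd_estimates).append(est)
    return report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_YES_NO = {"yes": 1, "no": 0, "y": 1, "n": 0, "true": 1, "false": 0}


def read_cohort_csv(path, config: AnalysisConfig) -> Cohort:
    """Read a patient-level CSV and map the configured columns onto the
    canonical cohort layout; binary columns are validated strictly."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"{path}: empty file") from exc
    if df.empty:
        raise CohortError(f"{path}: no data rows")
    required = [config.treatment_name, config.outcome_name,
                *config.covariate_names, *config.instrument_candidates]
    if config.cluster_name:
        required.append(config.cluster_name)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    for col in set(config.yes_no_columns) & set(df.columns):
        df[col] = df[col].astype(str).str.lower().map(_YES_NO)
    renames = {config.treatment_name: TREATMENT, config.outcome_name: OUTCOME}
    df = df.rename(columns=renames)
    if PATIENT_ID not in df.columns:
        df.insert(0, PATIENT_ID, np.arange(len(df)))
    cohort = Cohort(
        data=df,
        covariate_names=tuple(config.covariate_names),
        instrument_names=tuple(config.instrument_candidates),
        cluster_name=config.cluster_name,
    )
    return cohort.validate()


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.data.to_csv(path, index=False)


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the report tables as TSV files; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    est = report.estimates_frame()
    p = out / "estimates.tsv"
    est.to_csv(p, sep="\t", index=False)
    written.append(p)

    for name, table in (
        ("balance_pre", report.balance_pre),
        ("balance_post", report.balance_post),
        ("instruments", report.instrument_table),
    ):
        if table is None:
            continue
        p = out / f"{name}.tsv"
        table.to_csv(p, sep="\t")
        written.append(p)

    if report.errors:
        p = out / "errors.tsv"
        pd.Series(report.errors, name="message").rename_axis("stage").to_csv(p, sep="\t")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Config file parsing (used by the CLI)
# ---------------------------------------------------------------------------

def simulation_config_from_dict(d: dict) -> SimulationConfig:
    from .synthetic_data import CovariateSpec, OutcomeModel, TreatmentModel

    specs = tuple(
        CovariateSpec(
            name=s["name"], kind=s["kind"],
            location=float(s["location"]), scale=float(s.get("scale", 1.0)),
        )
        for s in d["covariate_specs"]
    )
    tm = d["treatment_model"]
    om = d["outcome_model"]
    return SimulationConfig(
        n_patients=int(d["n_patients"]),
        seed=int(d.get("seed", 0)),
        instrument_prevalence=float(d["instrument_prevalence"]),
        covariate_specs=specs,
        confounder_sd=float(d.get("confounder_sd", 0.0)),
        treatment_model=TreatmentModel(
            intercept=float(tm["intercept"]),
            instrument_coef=float(tm["instrument_coef"]),
            covariate_coefs={k: float(v) for k, v in tm.get("covariate_coefs", {}).items()},
            confounder_coef=float(tm.get("confounder_coef", 0.0)),
        ),
        outcome_model=OutcomeModel(
            intercept=float(om["intercept"]),
            treatment_effect=float(om["treatment_effect"]),
            covariate_coefs={k: float(v) for k, v in om.get("covariate_coefs", {}).items()},
            confounder_coef=float(om.get("confounder_coef", 0.0)),
        ),
        outcome_model_kind=d.get("outcome_model_kind", "logistic"),
        instrument_name=d.get("instrument_name", "instrument"),
        cluster_count=d.get("cluster_count"),
    )


def analysis_config_from_yaml(path) -> AnalysisConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    sim = d.get("simulation")
    return AnalysisConfig(
        covariate_names=tuple(d["covariate_names"]),
        instrument_candidates=tuple(d["instrument_candidates"]),
        cohort_path=d.get("cohort_path"),
        simulation=simulation_config_from_dict(sim) if sim else None,
        treatment_name=d.get("treatment_name", TREATMENT),
        outcome_name=d.get("outcome_name", OUTCOME),
        cluster_name=d.get("cluster_name"),
        estimators=tuple(d.get("estimators", DEFAULT_ESTIMATORS)),
        bootstrap_iterations=int(d.get("bootstrap_iterations", 1000)),
        bootstrap_seed=int(d.get("bootstrap_seed", 0)),
        match_seed=int(d.get("match_seed", 0)),
        confidence_level=float(d.get("confidence_level", 0.95)),
        yes_no_columns=tuple(d.get("yes_no_columns", ())),
    )
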