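"""Minimal regression engine: OLS, logistic and probit fits with coefficient
covariances.

All multi-stage estimators in the package are built on these three fits.  The
heavy lifting is delegated to :mod:`statsmodels`; this module pins the
contracts the rest of the package relies on — an implicit leading intercept,
a strict full-rank requirement with named collinear columns, explicit
convergence and separation errors instead of silent garbage, and covariance
matrices on the usual maximum-likelihood scales
(:math:`\\hat\\sigma^2 (D^\\top D)^{-1}` for OLS, inverse observed information
for the binary families).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    ConvergenceError,
    DegenerateResponseError,
    RankDeficientDesignError,
    SeparationError,
)

INTERCEPT = "intercept"

#: |coefficient| bound, on standardized inputs, beyond which a logistic or
#: probit fit is declared separated rather than converged.
SEPARATION_COEF_BOUND = 15.0


@dataclass
class FitResult:
    family: str  # {"linear", "logistic", "probit"}
    coefficient_names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    fitted_values: np.ndarray  # response-scale predictions
    n_obs: int
    converged: bool

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.coefficient_names.index(name)])

    def se(self, name: str) -> float:
        i = self.coefficient_names.index(name)
        return float(np.sqrt(self.covariance[i, i]))


def _as_design(design, names):
    """Coerce covariates (no intercept) to (matrix, names)."""
    if isinstance(design, pd.DataFrame):
        mat = design.to_numpy(dtype=float)
        names = tuple(str(c) for c in design.columns)
    else:
        mat = np.asarray(design, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if mat.ndim != 2:
            raise ValueError("design must be 2-dimensional")
        if names is None:
            names = tuple(f"x{i + 1}" for i in range(mat.shape[1]))
        else:
            names = tuple(names)
    if len(names) != mat.shape[1]:
        raise ValueError("number of names does not match design columns")
    return mat, names


def _check_shapes(mat: np.ndarray, y: np.ndarray):
    n, p = mat.shape
    if len(y) != n:
        raise ValueError(f"design has {n} rows but response has {len(y)}")
    if n < p + 1:
        raise RankDeficientDesignError(
            f"n={n} observations cannot identify {p + 1} coefficients"
        )


def _check_rank(mat: np.ndarray, names: tuple[str, ...]):
    """Full design = [1 | mat]; raise naming collinear columns if deficient."""
    full = np.column_stack([np.ones(len(mat)), mat])
    _, r = np.linalg.qr(full)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(full.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        all_names = (INTERCEPT,) + names
        labels = tuple(all_names[i] for i in bad)
        raise RankDeficientDesignError(
            f"design is rank deficient; collinear columns: {labels}", columns=labels
        )
    return full


def _check_binary(y: np.ndarray):
    vals = np.unique(y)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("binary-family response must be coded 0/1")
    if vals.size < 2:
        raise DegenerateResponseError(
            f"response takes the single value {vals[0]:g}; model not estimable"
        )


def _check_separation(mat: np.ndarray, coefs: np.ndarray):
    """Diverging standardized slopes indicate (quasi-)complete separation."""
    if mat.shape[1] == 0:
        return
    sds = mat.std(axis=0, ddof=1)
    scaled = np.abs(coefs[1:]) * np.where(sds > 0, sds, 1.0)
    if np.any(scaled > SEPARATION_COEF_BOUND):
        raise SeparationError(
            "separation suspected: standardized |coefficient| exceeds "
            f"{SEPARATION_COEF_BOUND:g}"
        )


def fit_linear(design, response, names=None) -> FitResult:
    """Ordinary least squares of ``response`` on an intercept plus ``design``.

    Covariance is :math:`\\hat\\sigma^2 (D^\\top D)^{-1}` with the residual
    variance on ``n - p`` degrees of freedom.
    """
    mat, names = _as_design(design, names)
    y = np.asarray(response, dtype=float)
    _check_shapes(mat, y)
    full = _check_rank(mat, names)
    res = sm.OLS(y, full).fit()
    return FitResult(
        family="linear",
        coefficient_names=(INTERCEPT,) + names,
        coefficients=np.asarray(res.params, dtype=float),
        covariance=np.asarray(res.cov_params(), dtype=float),
        fitted_values=np.asarray(res.fittedvalues, dtype=float),
        n_obs=len(y),
        converged=True,
    )


def _fit_binary(design, response, names, family: str) -> FitResult:
    mat, names = _as_design(design, names)
    y = np.asarray(response, dtype=float)
    _check_shapes(mat, y)
    full = _check_rank(mat, names)
    _check_binary(y)
    model_cls = sm.Logit if family == "logistic" else sm.Probit
    model = model_cls(y, full)
    try:
        res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=0)
    except PerfectSeparationError as exc:  # statsmodels' own detection
        raise SeparationError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"{family} fit failed: {exc}") from exc
    coefs = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(coefs)):
        raise ConvergenceError(f"{family} fit produced non-finite coefficients")
    _check_separation(mat, coefs)
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"{family} fit did not converge in {res.mle_retvals.get('iterations')} iterations"
        )
    return FitResult(
        family=family,
        coefficient_names=(INTERCEPT,) + names,
        coefficients=coefs,
        covariance=np.asarray(res.cov_params(), dtype=float),
        fitted_values=np.asarray(res.predict(full), dtype=float),
        n_obs=len(y),
        converged=True,
    )


def fit_logistic(design, response, names=None) -> FitResult:
    """Maximum-likelihood logistic regression (implicit intercept)."""
    return _fit_binary(design, response, names, "logistic")


def fit_probit(design, response, names=None) -> FitResult:
    """Maximum-likelihood probit regression (implicit intercept)."""
    return _fit_binary(design, response, names, "probit")
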