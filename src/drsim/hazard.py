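"""Logistic progression model: probability evaluation, intercept
calibration, and maximum-likelihood fitting for parameter recovery.

The published model carries three predictors (diabetes duration,
nephropathy, BMI); its intercept is recovered by calibrating the mean
predicted probability to an observed prevalence, since only the odds
ratios are available.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .domain import LogisticHazard, PredictorProfile, ValidationError

__all__ = [
    "FitResult",
    "progression_probability",
    "calibrate_intercept",
    "fit_logistic",
    "design_matrix",
    "SeparationWarning",
]

#: Published odds ratios of the three significant predictors.
DEFAULT_ODDS_RATIOS = {"dm_duration": 1.059, "nephropathy": 2.163, "bmi": 0.961}


class SeparationWarning(UserWarning):
    """Raised as a warning when the likelihood has no finite maximizer."""


def progression_probability(hazard: LogisticHazard, profile: PredictorProfile) -> float:
    """Evaluate p = 1 / (1 + exp(-(beta . x + m))) for one agent.

    Strictly inside (0, 1) for finite inputs; monotone in each predictor
    according to the sign of its coefficient.
    """
    eta = hazard.linear_predictor(profile)
    p = float(expit(eta))
    # expit saturates to exactly 0/1 in float for |eta| > ~745; clamp to
    # the open interval so downstream odds are finite.
    tiny = np.finfo(float).tiny
    return min(max(p, tiny), 1.0 - np.finfo(float).epsneg)


def _linear_predictors(beta: dict[str, float], profiles: Sequence[PredictorProfile]) -> np.ndarray:
    return np.array(
        [sum(b * p.value(k) for k, b in beta.items()) for p in profiles], dtype=float
    )


def calibrate_intercept(
    beta: dict[str, float],
    profiles: Sequence[PredictorProfile],
    target_mean_probability: float,
    tol: float = 1e-10,
) -> float:
    """Find the intercept m so that mean_i expit(beta.x_i + m) == target.

    The mean predicted probability is strictly increasing in m, so the
    root is unique; it is found by bracketed root-finding to ``tol``.
    """
    if not profiles:
        raise ValidationError("profiles must be non-empty")
    if not (0.0 < target_mean_probability < 1.0):
        raise ValidationError(
            f"target mean probability must be in (0, 1): {target_mean_probability}"
        )
    eta = _linear_predictors(beta, profiles)
    return calibrate_intercept_from_eta(eta, target_mean_probability, tol=tol)


def calibrate_intercept_from_eta(
    eta: np.ndarray, target: float, tol: float = 1e-10
) -> float:
    """Same root-find given precomputed coefficient-only linear predictors."""

    def gap(m: float) -> float:
        return float(np.mean(expit(eta + m))) - target

    lo, hi = -1.0, 1.0
    for _ in range(200):
        if gap(lo) < 0:
            break
        lo *= 2.0
    for _ in range(200):
        if gap(hi) > 0:
            break
        hi *= 2.0
    if not (gap(lo) < 0 < gap(hi)):
        raise ArithmeticError("could not bracket the calibration target")
    return float(optimize.brentq(gap, lo, hi, xtol=tol, rtol=8.9e-16))


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit with Wald inference."""

    coefficients: dict[str, float]
    intercept: float
    std_errors: dict[str, float]
    intercept_se: float
    odds_ratios: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0
    log_likelihood: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        def safe_exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf

        if not self.odds_ratios:
            self.odds_ratios = {k: safe_exp(v) for k, v in self.coefficients.items()}
        if not self.ci95:
            z = 1.959963984540054  # Phi^{-1}(0.975)
            self.ci95 = {
                k: (
                    safe_exp(v - z * self.std_errors[k]),
                    safe_exp(v + z * self.std_errors[k]),
                )
                for k, v in self.coefficients.items()
            }

    def to_hazard(self) -> LogisticHazard:
        return LogisticHazard(dict(self.coefficients), self.intercept)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "std_errors": self.std_errors,
            "intercept_se": self.intercept_se,
            "odds_ratios": self.odds_ratios,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def design_matrix(
    profiles: Sequence[PredictorProfile], columns: Sequence[str]
) -> np.ndarray:
    return np.array([[p.value(c) for c in columns] for p in profiles], dtype=float)


def fit_logistic(
    outcomes: np.ndarray,
    design: np.ndarray,
    columns: Sequence[str],
    max_iter: int = 100,
    ll_tol: float = 1e-10,
) -> FitResult:
    """Fit a logistic regression by iteratively reweighted least squares.

    ``design`` holds one column per named predictor; an intercept column is
    added internally.  Convergence requires the relative change in
    log-likelihood to fall below ``ll_tol`` within ``max_iter`` iterations.
    Perfect separation is reported via ``converged=False`` and a
    :class:`SeparationWarning`; a singular design raises.
    """
    y = np.asarray(outcomes, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design must be a 2-D array")
    if len(columns) != X.shape[1]:
        raise ValidationError("column names do not match design width")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("outcomes and design have different lengths")
    if X.shape[0] < X.shape[1] + 1:
        raise ValidationError("fewer rows than parameters")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))) or uniq.size < 2:
        raise ValidationError("outcomes must contain both 0 and 1")

    Xi = np.column_stack([np.ones(X.shape[0]), X])
    k = Xi.shape[1]

    # A singular design has no unique MLE regardless of the outcomes.
    if np.linalg.matrix_rank(Xi) < k:
        raise np.linalg.LinAlgError("design matrix is singular (collinear columns)")

    theta = np.zeros(k)
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xi @ theta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        # working response for the Newton step
        wz = w * eta + (y - mu)
        XtWX = Xi.T @ (Xi * w[:, None])
        try:
            theta_new = np.linalg.solve(XtWX, Xi.T @ wz)
        except np.linalg.LinAlgError:
            # weights collapsed: fitted probabilities at 0/1 -> separation
            break
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.any(np.abs(theta_new) > 500.0):
            theta = theta_new
            break
        theta = theta_new
        if math.isfinite(ll_old) and abs(ll - ll_old) <= ll_tol * (abs(ll_old) + ll_tol):
            converged = True
            break
        ll_old = ll

    eta = Xi @ theta
    mu = expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    w = mu * (1.0 - mu)
    XtWX = Xi.T @ (Xi * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible perfect separation)",
            SeparationWarning,
            stacklevel=2,
        )

    names = list(columns)
    return FitResult(
        coefficients={n: float(theta[i + 1]) for i, n in enumerate(names)},
        intercept=float(theta[0]),
        std_errors={n: float(se[i + 1]) for i, n in enumerate(names)},
        intercept_se=float(se[0]),
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll,
        n_obs=int(y.shape[0]),
    )
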