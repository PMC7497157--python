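"""Binomial logistic regression by Newton-Raphson maximum likelihood.

The model gives P(coded-one sex) = 1/(1 + exp(-(b0 + b1*x1 + ... + bn*xn))).
Female is coded 1 by default so the fitted equation reads as P(Female),
matching the convention of publishing sex-estimation equations as a female
probability; the coding is recorded in the model file so equations under
the opposite convention load correctly.

Metric skeletal variables can come close to separating the sexes, which
drives MLE coefficients toward infinity. Rather than crash, the fitter
flags such fits (any |linear predictor| beyond ``SEPARATION_LIMIT``) with
``converged = False`` and a warning; predictions remain usable as
sign-rule classifications.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .io import FEMALE, MALE, ModelFile, ReferenceSample
from .discriminant import Classification, _check_decision_probability, _threshold_call

SEPARATION_LIMIT = 30.0
MAX_ITER = 100
STEP_TOL = 1e-8
LOGLIK_RELTOL = 1e-10


class SeparationWarning(UserWarning):
    """The data (nearly) perfectly separate the sexes; MLE is unstable."""


@dataclass
class LogisticModel:
    variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    coded_one_sex: str
    log_likelihood: float
    aic: float
    n: int
    converged: bool
    iterations: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    intercept_se: float | None = None

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[v] for v in self.variables])

    def to_model_file(self, **extra_metadata) -> ModelFile:
        meta = {
            "coded_one_sex": self.coded_one_sex,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n": self.n,
            "converged": self.converged,
            "iterations": self.iterations,
            "standard_errors": dict(self.standard_errors),
            "intercept_se": self.intercept_se,
            **extra_metadata,
        }
        return ModelFile(
            model_kind="logr",
            variables=list(self.variables),
            coefficients=dict(self.coefficients),
            intercept=self.intercept,
            metadata=meta,
        )

    @classmethod
    def from_model_file(cls, model_file: ModelFile) -> "LogisticModel":
        if model_file.model_kind != "logr":
            raise ValueError(f"expected a logr model file, got {model_file.model_kind!r}")
        meta = model_file.metadata
        return cls(
            variables=list(model_file.variables),
            coefficients=dict(model_file.coefficients),
            intercept=model_file.intercept,
            coded_one_sex=meta.get("coded_one_sex", FEMALE),
            log_likelihood=float(meta.get("log_likelihood", float("nan"))),
            aic=float(meta.get("aic", float("nan"))),
            n=int(meta.get("n", 0)),
            converged=bool(meta.get("converged", True)),
            iterations=int(meta.get("iterations", 0)),
            standard_errors=dict(meta.get("standard_errors", {})),
            intercept_se=meta.get("intercept_se"),
        )


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # sum of y*log(p) + (1-y)*log(1-p), computed stably from the linear predictor
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_newton(
    design: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Newton-Raphson on an explicit design matrix (first column intercept).

    Returns (beta, covariance, log_likelihood, iterations, converged).
    Shared with the logit-linearity diagnostic, which fits augmented
    designs directly.
    """
    n, k = design.shape
    beta = np.zeros(k)
    loglik = _log_likelihood(y, design @ beta)
    converged = False
    iterations = 0
    cov = np.full((k, k), np.nan)
    for iterations in range(1, MAX_ITER + 1):
        eta = design @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        gradient = design.T @ (y - p)
        hessian = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hessian, gradient)
        except np.linalg.LinAlgError:
            # curvature (near-)vanished, typically under separation or a
            # barely identified augmented design; take a pseudoinverse step
            step = np.linalg.pinv(hessian) @ gradient
        if not np.all(np.isfinite(step)):
            break
        beta = beta + step
        new_loglik = _log_likelihood(y, design @ beta)
        if np.max(np.abs(step)) < STEP_TOL or (
            abs(new_loglik - loglik) < LOGLIK_RELTOL * (abs(loglik) + LOGLIK_RELTOL)
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    eta = design @ beta
    if np.max(np.abs(eta)) > SEPARATION_LIMIT:
        converged = False
        warnings.warn(
            "fitted linear predictor exceeds the separation limit; the data "
            "(nearly) perfectly separate the groups and coefficients are "
            "unstable",
            SeparationWarning,
            stacklevel=3,
        )
    p = expit(eta)
    w = p * (1.0 - p)
    hessian = (design * w[:, None]).T @ design
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hessian)
    return beta, cov, _log_likelihood(y, eta), iterations, converged


def fit_logr(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    coded_one_sex: str = FEMALE,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of sex on the selected measurements."""
    if coded_one_sex not in (FEMALE, MALE):
        raise ValueError(f"coded_one_sex must be F or M, got {coded_one_sex!r}")
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    y = (sample.sex_array() == coded_one_sex).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one record of each sex")
    constant = [v for v, s in zip(variables, x.std(axis=0)) if s == 0]
    if constant:
        raise ValueError(f"variable(s) constant across the sample: {constant}")
    design = np.column_stack([np.ones(len(x)), x])
    beta, cov, loglik, iterations, converged = _fit_newton(design, y)
    k = len(variables) + 1  # intercept counts as a parameter
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
    return LogisticModel(
        variables=variables,
        coefficients={v: float(b) for v, b in zip(variables, beta[1:])},
        intercept=float(beta[0]),
        coded_one_sex=coded_one_sex,
        log_likelihood=loglik,
        aic=2.0 * k - 2.0 * loglik,
        n=len(y),
        converged=converged,
        iterations=iterations,
        standard_errors={v: float(s) for v, s in zip(variables, se[1:])},
        intercept_se=float(se[0]) if np.isfinite(se[0]) else None,
    )


def predict_prob(
    model: LogisticModel, measurements: Mapping[str, float]
) -> tuple[float, float]:
    """(P_F, P_M) for one individual; the complement rule holds exactly."""
    missing = [v for v in model.variables if v not in measurements]
    if missing:
        raise ValueError(f"missing measurement(s): {missing}")
    eta = model.intercept + sum(
        model.coefficients[v] * measurements[v] for v in model.variables
    )
    p_one = float(expit(eta))
    if model.coded_one_sex == FEMALE:
        return p_one, 1.0 - p_one
    return 1.0 - p_one, p_one


def odds_ratios(model: LogisticModel) -> dict[str, float]:
    """Per-variable odds ratio exp(b_i): multiplicative change in the odds
    of the coded-one sex per mm; 1 means no effect."""
    return {v: math.exp(b) for v, b in model.coefficients.items()}


def classify_logr(
    model: LogisticModel,
    measurements: Mapping[str, float],
    decision_probability: float = 0.5,
) -> Classification:
    """Call sex when the predicted probability reaches the decision level."""
    _check_decision_probability(decision_probability)
    p_f, p_m = predict_prob(model, measurements)
    return _threshold_call(p_f, p_m, decision_probability)
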