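"""Two-group linear discriminant analysis on a standardized score axis.

The discriminant score is the affine function D = b0 + b1*x1 + ... + bn*xn.
Coefficients are the pooled-within-covariance direction Sigma_w^-1 (mu_M -
mu_F), rescaled so the pooled within-group variance of D is exactly 1, and
the intercept places the midpoint of the two group score means at 0. Under
equal priors the classical sectioning point is therefore the score 0
(female < 0 < male), and posterior sex probabilities follow from plugging
unit-variance normal densities for the two groups into Bayes' rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .io import FEMALE, MALE, ModelFile, ReferenceSample

_MAX_CONDITION = 1e12


@dataclass
class Classification:
    """A sex call with its supporting probabilities."""

    label: str  # "F", "M" or "indeterminate"
    p_f: float
    p_m: float

    @property
    def probability(self) -> float:
        """Probability of the called sex (max of the two when indeterminate)."""
        return max(self.p_f, self.p_m)


@dataclass
class LinearDiscriminantModel:
    """Fitted two-group LDA with the unit-within-variance convention.

    ``score_mean_f``/``score_mean_m`` are the group means of D; with the
    midpoint-centred intercept they sit symmetrically at -d/2 and +d/2,
    where d is the Mahalanobis distance between group centroids.
    """

    variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    score_mean_f: float
    score_mean_m: float
    priors: tuple[float, float]  # (pi_F, pi_M)
    n_f: int
    n_m: int

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.priors), 1.0, abs_tol=1e-9):
            raise ValueError(f"priors must sum to 1, got {self.priors}")
        if not self.score_mean_f < self.score_mean_m:
            raise ValueError("male score mean must exceed female score mean")

    @property
    def separation(self) -> float:
        """Mahalanobis distance between group centroids on the score axis."""
        return self.score_mean_m - self.score_mean_f

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[v] for v in self.variables])

    def to_model_file(self, **extra_metadata) -> ModelFile:
        meta = {
            "score_mean_f": self.score_mean_f,
            "score_mean_m": self.score_mean_m,
            "priors": {"F": self.priors[0], "M": self.priors[1]},
            "n": {"F": self.n_f, "M": self.n_m},
            "scaling": "unit pooled within-group score variance",
            **extra_metadata,
        }
        return ModelFile(
            model_kind="lda",
            variables=list(self.variables),
            coefficients=dict(self.coefficients),
            intercept=self.intercept,
            metadata=meta,
        )

    @classmethod
    def from_model_file(cls, model_file: ModelFile) -> "LinearDiscriminantModel":
        if model_file.model_kind != "lda":
            raise ValueError(f"expected an lda model file, got {model_file.model_kind!r}")
        meta = model_file.metadata
        priors = meta.get("priors", {"F": 0.5, "M": 0.5})
        n = meta.get("n", {"F": 0, "M": 0})
        return cls(
            variables=list(model_file.variables),
            coefficients=dict(model_file.coefficients),
            intercept=model_file.intercept,
            score_mean_f=float(meta["score_mean_f"]),
            score_mean_m=float(meta["score_mean_m"]),
            priors=(float(priors["F"]), float(priors["M"])),
            n_f=int(n["F"]),
            n_m=int(n["M"]),
        )


def _fit_lda_core(
    x: np.ndarray, is_male: np.ndarray, priors: tuple[float, float]
) -> tuple[np.ndarray, float, float, float]:
    """Array-level fit; returns (coefficients, intercept, mean_F, mean_M).

    Kept separate from :func:`fit_lda` so resampling loops (LOOCV,
    bootstrap) avoid record-object overhead.
    """
    xf, xm = x[~is_male], x[is_male]
    if len(xf) < 2 or len(xm) < 2:
        raise ValueError("need at least 2 records per sex to fit LDA")
    mu_f = xf.mean(axis=0)
    mu_m = xm.mean(axis=0)
    # pooled within-group covariance, denominator n_F + n_M - 2
    dev_f = xf - mu_f
    dev_m = xm - mu_m
    sw = (dev_f.T @ dev_f + dev_m.T @ dev_m) / (len(x) - 2)
    sw = np.atleast_2d(sw)
    if np.linalg.cond(sw) > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            "pooled within-group covariance is (near-)singular; "
            "variables may be collinear"
        )
    direction = np.linalg.solve(sw, mu_m - mu_f)
    score_var = float(direction @ sw @ direction)
    if score_var <= 0:
        raise np.linalg.LinAlgError("degenerate within-group score variance")
    b = direction / math.sqrt(score_var)  # unit pooled within-group variance
    midpoint = (mu_f + mu_m) / 2.0
    b0 = -float(b @ midpoint)
    mean_f = float(b @ mu_f) + b0
    mean_m = float(b @ mu_m) + b0
    return b, b0, mean_f, mean_m


def fit_lda(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    priors: tuple[float, float] | str = "equal",
) -> LinearDiscriminantModel:
    """Fit the two-group discriminant with an uninformative prior by default.

    ``priors`` may be the string ``"equal"`` (0.5/0.5), ``"proportional"``
    (group frequencies), or an explicit ``(pi_F, pi_M)`` pair summing to 1.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    n_f, n_m = int((~is_male).sum()), int(is_male.sum())
    if priors == "equal":
        pi = (0.5, 0.5)
    elif priors == "proportional":
        pi = (n_f / len(x), n_m / len(x))
    else:
        pi = (float(priors[0]), float(priors[1]))
        if not math.isclose(sum(pi), 1.0, abs_tol=1e-9):
            raise ValueError(f"priors must sum to 1, got {pi}")
    b, b0, mean_f, mean_m = _fit_lda_core(x, is_male, pi)
    return LinearDiscriminantModel(
        variables=variables,
        coefficients={v: float(c) for v, c in zip(variables, b)},
        intercept=b0,
        score_mean_f=mean_f,
        score_mean_m=mean_m,
        priors=pi,
        n_f=n_f,
        n_m=n_m,
    )


def discriminant_score(
    model: LinearDiscriminantModel | ModelFile, measurements: Mapping[str, float]
) -> float:
    """Evaluate D = b0 + sum(b_i * x_i) for one set of measurements.

    Accepts either a fitted model or a loaded model file, so published
    equations can be applied without refitting.
    """
    missing = [v for v in model.variables if v not in measurements]
    if missing:
        raise ValueError(f"missing measurement(s): {missing}")
    return float(
        model.intercept
        + sum(model.coefficients[v] * measurements[v] for v in model.variables)
    )


def _posterior_from_score(
    score: float | np.ndarray,
    mean_f: float,
    mean_m: float,
    priors: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    pi_f, pi_m = priors
    if not math.isclose(pi_f + pi_m, 1.0, abs_tol=1e-9):
        raise ValueError(f"priors must sum to 1, got {priors}")
    d = np.asarray(score, dtype=float)
    # log odds male vs female under unit-variance normal score densities
    log_odds = math.log(pi_m / pi_f) + (mean_m - mean_f) * d + (mean_f**2 - mean_m**2) / 2.0
    p_m = expit(log_odds)
    return 1.0 - p_m, p_m


def lda_posterior(
    model: LinearDiscriminantModel, score: float
) -> tuple[float, float]:
    """Plug-in posterior (P_F, P_M) at a discriminant score.

    Each group's score density is normal with unit variance centred at the
    group score mean; Bayes' rule with the model priors gives the
    posterior. With equal priors this is a logistic function of the score
    with slope equal to the centroid separation.
    """
    p_f, p_m = _posterior_from_score(
        score, model.score_mean_f, model.score_mean_m, model.priors
    )
    return float(p_f), float(p_m)


def score_cutoff_at_probability(
    model: LinearDiscriminantModel, p: float, sex: str = MALE
) -> float:
    """Exact score at which the posterior for ``sex`` equals ``p``.

    Analytic inversion of the plug-in posterior; with equal priors and
    ``p = 0.5`` this is the classical sectioning point 0, and the male and
    female cutoffs are symmetric about it.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability level must lie in (0, 1), got {p}")
    pi_f, pi_m = model.priors
    sep = model.separation
    const = math.log(pi_m / pi_f) + (model.score_mean_f**2 - model.score_mean_m**2) / 2.0
    target = logit(p) if sex == MALE else -logit(p)
    return float((target - const) / sep)


def classify_lda(
    model: LinearDiscriminantModel,
    measurements: Mapping[str, float],
    decision_probability: float = 0.5,
) -> Classification:
    """Call sex when the winning posterior reaches the decision probability.

    At 0.5 this reduces to the sign-of-score rule; below the threshold the
    call is "indeterminate". An exact posterior tie (score at the
    sectioning point) is also indeterminate.
    """
    _check_decision_probability(decision_probability)
    d = discriminant_score(model, measurements)
    p_f, p_m = lda_posterior(model, d)
    return _threshold_call(p_f, p_m, decision_probability)


def _check_decision_probability(decision_probability: float) -> None:
    if not 0.5 <= decision_probability < 1.0:
        raise ValueError(
            f"decision probability must lie in [0.5, 1), got {decision_probability}"
        )


def _threshold_call(p_f: float, p_m: float, decision_probability: float) -> Classification:
    if p_f == p_m:
        return Classification("indeterminate", p_f, p_m)
    winner, p_win = (FEMALE, p_f) if p_f > p_m else (MALE, p_m)
    if p_win >= decision_probability:
        return Classification(winner, p_f, p_m)
    return Classification("indeterminate", p_f, p_m)
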