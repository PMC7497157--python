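"""Diagnostics for the discriminant and logistic modelling assumptions.

Covers multicollinearity (variance inflation factors), homogeneity of the
per-sex covariance matrices (Box's M with its chi-square approximation),
multivariate outliers (Mahalanobis distance against a chi-square
quantile), and linearity between each predictor and the logit of sex
(Box-Tidwell-style x*ln(x) interaction terms in an augmented logistic
model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import FEMALE, MALE, ReferenceSample
from .logistic import SeparationWarning, _fit_newton


def vif(sample: ReferenceSample, variables: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factor per variable, sexes pooled.

    VIF_j = 1/(1 - R^2_j) where R^2_j comes from regressing variable j on
    the remaining variables (with intercept). 1 means no collinearity.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    n, p = x.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} records for {p} variables")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    out: dict[str, float] = {}
    for j, name in enumerate(variables):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        out[name] = 1.0 / (1.0 - r2)
    return out


@dataclass
class BoxMResult:
    statistic: float  # M
    chi2: float
    df: int
    p_value: float


def box_m(sample: ReferenceSample, variables: Sequence[str] | None = None) -> BoxMResult:
    """Box's M test for equality of the two sexes' covariance matrices.

    M = (n-k) ln|S_pooled| - sum_g (n_g - 1) ln|S_g|, referred to a
    chi-square with (k-1) p (p+1)/2 degrees of freedom after Box's
    small-sample scaling factor.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    groups = [x[~is_male], x[is_male]]
    p = len(variables)
    k = len(groups)
    n = len(x)
    log_dets = []
    pooled = np.zeros((p, p))
    for g in groups:
        if len(g) <= p:
            raise ValueError(
                f"group size {len(g)} must exceed the number of variables {p}"
            )
        s = np.cov(g, rowvar=False, ddof=1)
        s = np.atleast_2d(s)
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular group covariance matrix")
        log_dets.append(logdet)
        pooled += (len(g) - 1) * s
    pooled /= n - k
    sign, log_det_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular pooled covariance matrix")
    m_stat = (n - k) * log_det_pooled - sum(
        (len(g) - 1) * ld for g, ld in zip(groups, log_dets)
    )
    c = (sum(1.0 / (len(g) - 1) for g in groups) - 1.0 / (n - k)) * (
        (2.0 * p**2 + 3.0 * p - 1.0) / (6.0 * (p + 1.0) * (k - 1.0))
    )
    chi2 = m_stat * (1.0 - c)
    df = (k - 1) * p * (p + 1) // 2
    p_value = float(stats.chi2.sf(chi2, df))
    return BoxMResult(statistic=float(m_stat), chi2=float(chi2), df=df, p_value=p_value)


@dataclass
class OutlierRecord:
    id: str
    sex: str
    distance_sq: float
    flagged: bool


@dataclass
class MahalanobisReport:
    quantile: float
    cutoff: float  # chi-square quantile on squared distance
    pooled: list[OutlierRecord]
    by_sex: dict[str, list[OutlierRecord]]

    @property
    def flagged_ids(self) -> list[str]:
        """Ids flagged against the pooled mean/covariance."""
        return [r.id for r in self.pooled if r.flagged]

    @property
    def flagged_ids_by_sex(self) -> list[str]:
        return sorted(
            {r.id for recs in self.by_sex.values() for r in recs if r.flagged}
        )


def mahalanobis_outliers(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    quantile: float = 0.975,
) -> MahalanobisReport:
    """Multivariate outliers by classical squared Mahalanobis distance.

    Distances are computed both to the pooled (whole-sample) mean with the
    whole-sample covariance, and within each sex to that sex's own
    mean/covariance; an individual is flagged when its squared distance
    exceeds the chi-square quantile with p degrees of freedom.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    ids = sample.ids()
    sexes = sample.sex_array()
    p = len(variables)
    cutoff = float(stats.chi2.ppf(quantile, p))

    def distances(xs: np.ndarray) -> np.ndarray:
        mu = xs.mean(axis=0)
        cov = np.atleast_2d(np.cov(xs, rowvar=False, ddof=1))
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError("singular covariance matrix")
        dev = xs - mu
        return np.einsum("ij,ij->i", dev @ np.linalg.inv(cov), dev)

    d_pooled = distances(x)
    pooled = [
        OutlierRecord(i, s, float(d), bool(d > cutoff))
        for i, s, d in zip(ids, sexes, d_pooled)
    ]
    by_sex: dict[str, list[OutlierRecord]] = {}
    for sex in (FEMALE, MALE):
        mask = sexes == sex
        d = distances(x[mask])
        by_sex[sex] = [
            OutlierRecord(i, sex, float(di), bool(di > cutoff))
            for i, di in zip(np.asarray(ids)[mask], d)
        ]
    return MahalanobisReport(quantile=quantile, cutoff=cutoff, pooled=pooled, by_sex=by_sex)


@dataclass
class LogitLinearityResult:
    """Wald tests of the x*ln(x) interaction terms; a small p-value means
    the logit is not linear in that predictor."""

    tests: dict[str, tuple[float, float]]  # variable -> (z, p)
    joint: bool
    separation_flagged: bool


def logit_linearity(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    joint: bool = True,
) -> LogitLinearityResult:
    """Box-Tidwell-style check of linearity on the logit scale.

    Fits a logistic regression of sex (F coded 1) on the main effects plus
    an x*ln(x) term for each variable — jointly in one augmented model by
    default, or one variable at a time — and reports the Wald z and
    p-value of each interaction term.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    x = sample.matrix(variables)
    if np.any(x <= 0):
        raise ValueError("all measurements must be positive for the log terms")
    for j, name in enumerate(variables):
        if np.std(x[:, j]) == 0:
            raise ValueError(
                f"variable {name!r} is constant; its log term is collinear "
                "with the intercept"
            )
    y = (sample.sex_array() == FEMALE).astype(float)
    n = len(x)
    xlogx = x * np.log(x)

    def wald_for(design: np.ndarray, positions: list[int]) -> tuple[list[tuple[float, float]], bool]:
        flagged = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", SeparationWarning)
            beta, cov, *_ = _fit_newton(design, y)
            if any(issubclass(w.category, SeparationWarning) for w in caught):
                flagged = True
        out = []
        for pos in positions:
            se = math.sqrt(cov[pos, pos])
            z = beta[pos] / se
            out.append((float(z), float(2.0 * stats.norm.sf(abs(z)))))
        return out, flagged

    tests: dict[str, tuple[float, float]] = {}
    separation = False
    if joint:
        design = np.column_stack([np.ones(n), x, xlogx])
        positions = [1 + len(variables) + j for j in range(len(variables))]
        results, separation = wald_for(design, positions)
        tests = dict(zip(variables, results))
    else:
        for j, name in enumerate(variables):
            design = np.column_stack([np.ones(n), x, xlogx[:, [j]]])
            (res,), flagged = wald_for(design, [1 + len(variables)])
            separation = separation or flagged
            tests[name] = res
    return LogitLinearityResult(tests=tests, joint=joint, separation_flagged=separation)


@dataclass
class AssumptionReport:
    variables: list[str]
    vif: dict[str, float]
    box_m: BoxMResult
    outliers: MahalanobisReport
    logit_linearity: LogitLinearityResult

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "vif": self.vif,
            "box_m": {
                "M": self.box_m.statistic,
                "chi2": self.box_m.chi2,
                "df": self.box_m.df,
                "p": self.box_m.p_value,
            },
            "outliers": {
                "quantile": self.outliers.quantile,
                "cutoff": self.outliers.cutoff,
                "flagged_pooled": self.outliers.flagged_ids,
                "flagged_by_sex": self.outliers.flagged_ids_by_sex,
            },
            "logit_linearity": {
                v: {"z": z, "p": p} for v, (z, p) in self.logit_linearity.tests.items()
            },
        }

    def to_text(self) -> str:
        lines = [f"Assumption checks for variables: {', '.join(self.variables)}", ""]
        lines.append("Variance inflation factors (multicollinearity):")
        for v, value in self.vif.items():
            lines.append(f"  {v}: {value:.4f}")
        b = self.box_m
        lines.append(
            f"Box's M (homogeneity of covariance matrices): "
            f"chi2({b.df}) = {b.chi2:.4f}, p = {b.p_value:.4f}"
        )
        flagged = self.outliers.flagged_ids
        lines.append(
            "Mahalanobis outliers (pooled, chi2 "
            f"{self.outliers.quantile:.3f} quantile): "
            + (", ".join(flagged) if flagged else "none")
        )
        by_sex = self.outliers.flagged_ids_by_sex
        lines.append(
            "Mahalanobis outliers (within sex): "
            + (", ".join(by_sex) if by_sex else "none")
        )
        lines.append("Logit linearity (x*ln(x) interaction Wald tests):")
        for v, (z, p) in self.logit_linearity.tests.items():
            lines.append(f"  {v}: z = {z:.3f}, p = {p:.4f}")
        return "\n".join(lines)


def run_assumption_checks(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    outlier_quantile: float = 0.975,
) -> AssumptionReport:
    """All four diagnostics bundled into one report."""
    variables = list(variables) if variables is not None else list(sample.variables)
    return AssumptionReport(
        variables=variables,
        vif=vif(sample, variables),
        box_m=box_m(sample, variables),
        outliers=mahalanobis_outliers(sample, variables, quantile=outlier_quantile),
        logit_linearity=logit_linearity(sample, variables),
    )
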