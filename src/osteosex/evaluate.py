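"""Model evaluation: leave-one-out cross-validation, threshold-stratified
accuracy, the B and Q predictive indices, the sample-size experiment and
descriptive group comparisons.

Accuracy at a decision probability counts only individuals whose winning
probability reaches that level ("retained"); the rest are indeterminate.
The B index is one minus the mean squared error between predicted
probabilities and outcomes (1 = perfect, 0.75 at uniform-chance 0.5
predictions); the Q index is the mean of 1 + log2 of the probability
assigned to the true sex (1 = perfect, 0 = chance, negative = worse than
chance).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import FEMALE, MALE, ReferenceSample
from .discriminant import _fit_lda_core, _posterior_from_score
from .logistic import SeparationWarning, _fit_newton

Q_CLAMP_EPS = 1e-15


# ---------------------------------------------------------------------------
# scoring rules


def brier_index(probabilities: Sequence[float], outcomes: Sequence[int]) -> float:
    """B = 1 - mean((P_i - Y_i)^2) for class-1 probabilities P and binary
    outcomes Y."""
    p, y = _check_prob_outcome(probabilities, outcomes)
    return float(1.0 - np.mean((p - y) ** 2))


def q_index(probabilities: Sequence[float], outcomes: Sequence[int]) -> float:
    """Q = mean(1 + log2(P_i^Y_i (1-P_i)^(1-Y_i))).

    Probabilities are clamped to [eps, 1-eps] (eps = 1e-15) so a single
    (near-)separated fold cannot drive the index to -inf.
    """
    p, y = _check_prob_outcome(probabilities, outcomes)
    p = np.clip(p, Q_CLAMP_EPS, 1.0 - Q_CLAMP_EPS)
    log_true = np.where(y == 1, np.log2(p), np.log2(1.0 - p))
    return float(np.mean(1.0 + log_true))


def _check_prob_outcome(probabilities, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    if p.size == 0:
        raise ValueError("need at least one prediction")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcomes must be binary 0/1")
    return p, y


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass
class IndividualResult:
    id: str
    true_sex: str
    p_f: float
    p_m: float
    labels: dict[float, str]  # decision probability -> predicted label

    @property
    def prob_true_sex(self) -> float:
        return self.p_f if self.true_sex == FEMALE else self.p_m

    @property
    def sign_rule_label(self) -> str:
        if self.p_f > self.p_m:
            return FEMALE
        if self.p_m > self.p_f:
            return MALE
        return "indeterminate"


@dataclass
class AccuracySummary:
    """Proportions correct among retained individuals (None when no
    individual of that stratum was retained)."""

    retained_n: int
    misclassified: int
    overall: float | None
    female: float | None
    male: float | None

    def as_percent(self) -> dict:
        pct = lambda v: None if v is None else round(100.0 * v, 2)
        return {
            "retained_n": self.retained_n,
            "misclassified": self.misclassified,
            "overall_pct": pct(self.overall),
            "female_pct": pct(self.female),
            "male_pct": pct(self.male),
        }


@dataclass
class EvaluationReport:
    method: str
    variables: list[str]
    decision_probabilities: list[float]
    per_individual: list[IndividualResult]
    accuracy: dict[float, AccuracySummary]
    b: float
    q: float
    n_separated_folds: int = 0

    @property
    def n(self) -> int:
        return len(self.per_individual)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.per_individual:
            row = {
                "id": r.id,
                "true_sex": r.true_sex,
                "p_f": r.p_f,
                "p_m": r.p_m,
                "prob_true_sex": r.prob_true_sex,
            }
            for dp, label in r.labels.items():
                row[f"label_at_{dp}"] = label
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "method": self.method,
            "variables": self.variables,
            "n": self.n,
            "accuracy": {
                str(dp): acc.as_percent() for dp, acc in self.accuracy.items()
            },
            "b_index": self.b,
            "q_index": self.q,
            "n_separated_folds": self.n_separated_folds,
        }

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2))


class FoldError(RuntimeError):
    """A leave-one-out fold failed to fit; carries the fold id."""

    def __init__(self, fold_id: str, cause: Exception):
        super().__init__(f"LOOCV fold holding out {fold_id!r} failed: {cause}")
        self.fold_id = fold_id


def _loocv_probabilities(
    x: np.ndarray, is_male: np.ndarray, method: str
) -> tuple[np.ndarray, int]:
    """P(F) for each individual predicted from a model fitted on the rest.

    Returns the probabilities and the number of (near-)separated logistic
    folds. Deterministic; no randomness anywhere.
    """
    n = len(x)
    p_f = np.empty(n)
    n_separated = 0
    idx = np.arange(n)
    if method == "logr":
        design_full = np.column_stack([np.ones(n), x])
        y = (~is_male).astype(float)  # F coded 1
    for i in range(n):
        keep = idx != i
        if method == "lda":
            b, b0, mean_f, mean_m = _fit_lda_core(x[keep], is_male[keep], (0.5, 0.5))
            score = float(b @ x[i]) + b0
            pf_i, _ = _posterior_from_score(score, mean_f, mean_m, (0.5, 0.5))
            p_f[i] = float(pf_i)
        elif method == "logr":
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", SeparationWarning)
                beta, _, _, _, converged = _fit_newton(design_full[keep], y[keep])
                if any(issubclass(w.category, SeparationWarning) for w in caught):
                    n_separated += 1
            p_f[i] = float(expit(design_full[i] @ beta))
        else:
            raise ValueError(f"unknown method {method!r}; expected 'lda' or 'logr'")
    return p_f, n_separated


def loocv(
    sample: ReferenceSample,
    method: str,
    variables: Sequence[str] | None = None,
    decision_probabilities: Sequence[float] = (0.5,),
) -> EvaluationReport:
    """Leave-one-out evaluation of an LDA or logistic model specification.

    Each individual is predicted by a model refitted on the other n-1; the
    report carries per-individual probabilities, accuracy strata at each
    requested decision probability, and the B and Q indices computed on
    the cross-validated P(F) values.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    for dp in decision_probabilities:
        if not 0.5 <= dp < 1.0:
            raise ValueError(f"decision probability must lie in [0.5, 1), got {dp}")
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    ids = sample.ids()
    try:
        p_f, n_separated = _loocv_probabilities(x, is_male, method)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FoldError("<unknown>", exc) from exc

    per_individual = []
    for i, rid in enumerate(ids):
        true_sex = MALE if is_male[i] else FEMALE
        labels = {}
        for dp in decision_probabilities:
            winner_p = max(p_f[i], 1.0 - p_f[i])
            if p_f[i] == 0.5:
                labels[dp] = "indeterminate"
            elif winner_p >= dp:
                labels[dp] = FEMALE if p_f[i] > 0.5 else MALE
            else:
                labels[dp] = "indeterminate"
        per_individual.append(
            IndividualResult(
                id=rid, true_sex=true_sex, p_f=float(p_f[i]),
                p_m=float(1.0 - p_f[i]), labels=labels,
            )
        )

    accuracy = {
        dp: _accuracy_at(per_individual, dp) for dp in decision_probabilities
    }
    y = (~is_male).astype(int)  # F coded 1 for scoring rules
    return EvaluationReport(
        method=method,
        variables=variables,
        decision_probabilities=list(decision_probabilities),
        per_individual=per_individual,
        accuracy=accuracy,
        b=brier_index(p_f, y),
        q=q_index(p_f, y),
        n_separated_folds=n_separated,
    )


def _accuracy_at(per_individual: list[IndividualResult], dp: float) -> AccuracySummary:
    retained = [r for r in per_individual if r.labels[dp] != "indeterminate"]
    correct = [r for r in retained if r.labels[dp] == r.true_sex]

    def rate(subset_sex: str | None) -> float | None:
        pool = retained if subset_sex is None else [r for r in retained if r.true_sex == subset_sex]
        if not pool:
            return None
        return sum(1 for r in pool if r.labels[dp] == r.true_sex) / len(pool)

    return AccuracySummary(
        retained_n=len(retained),
        misclassified=len(retained) - len(correct),
        overall=rate(None),
        female=rate(FEMALE),
        male=rate(MALE),
    )


# ---------------------------------------------------------------------------
# sub-threshold accuracy


@dataclass
class SubthresholdAccuracy:
    """Sign-rule accuracy among individuals below the probability threshold.

    ``overall`` etc. are None ("not applicable") when the subset, or the
    per-sex stratum, is empty.
    """

    threshold: float
    n: int
    overall: float | None
    female: float | None
    male: float | None

    @property
    def applicable(self) -> bool:
        return self.n > 0


def subthreshold_accuracy(
    report: EvaluationReport, threshold: float = 0.8
) -> SubthresholdAccuracy:
    """Accuracy of the 0.5 sign rule restricted to individuals whose winning
    LOOCV probability fell below ``threshold``."""
    subset = [
        r for r in report.per_individual if max(r.p_f, r.p_m) < threshold
    ]

    def rate(sex: str | None) -> float | None:
        pool = subset if sex is None else [r for r in subset if r.true_sex == sex]
        if not pool:
            return None
        return sum(1 for r in pool if r.sign_rule_label == r.true_sex) / len(pool)

    return SubthresholdAccuracy(
        threshold=threshold,
        n=len(subset),
        overall=rate(None),
        female=rate(FEMALE),
        male=rate(MALE),
    )


# ---------------------------------------------------------------------------
# sample-size experiment


@dataclass
class SampleSizeResult:
    sizes: list[int]
    accuracies: list[list[float]]  # per size, one LOOCV accuracy per replicate
    mean_per_size: list[float]
    overall_mean: float
    overall_sd: float
    n_redraws: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"size": s, "replicate": k, "accuracy": a}
            for s, accs in zip(self.sizes, self.accuracies)
            for k, a in enumerate(accs)
        ]
        return pd.DataFrame(rows)


def sample_size_experiment(
    sample: ReferenceSample,
    method: str,
    variables: Sequence[str] | None = None,
    sizes: Sequence[int] | None = None,
    replicates_per_size: int = 100,
    seed: int | None = None,
) -> SampleSizeResult:
    """Accuracy under varying reference-sample size.

    For each size n, draw subsamples of n individuals with replacement
    (redrawing when a sex has fewer than 2 distinct individuals, or the
    subsample is degenerate for the fitter) and record the internal LOOCV
    accuracy at decision probability 0.5. Reports the accuracy curve plus
    the mean and SD over all runs. Deterministic under a fixed seed.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    sizes = list(sizes) if sizes is not None else list(range(10, len(sample) + 1))
    if min(sizes) < 4:
        raise ValueError("sizes below 4 cannot satisfy 2 records per sex")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(seed)
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    n = len(x)

    accuracies: list[list[float]] = []
    n_redraws = 0
    max_redraws = 1000 * replicates_per_size
    for size in sizes:
        per_size: list[float] = []
        for _ in range(replicates_per_size):
            while True:
                idx = rng.integers(0, n, size=size)
                males = idx[is_male[idx]]
                females = idx[~is_male[idx]]
                if len(np.unique(males)) < 2 or len(np.unique(females)) < 2:
                    n_redraws += 1
                elif _subsample_accuracy(x[idx], is_male[idx], method, per_size):
                    break
                else:
                    n_redraws += 1
                if n_redraws > max_redraws:
                    raise RuntimeError(
                        "persistent degenerate subsamples; sizes too small "
                        "for this sample"
                    )
        accuracies.append(per_size)
    flat = np.concatenate([np.asarray(a) for a in accuracies])
    return SampleSizeResult(
        sizes=sizes,
        accuracies=accuracies,
        mean_per_size=[float(np.mean(a)) for a in accuracies],
        overall_mean=float(flat.mean()),
        overall_sd=float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
        n_redraws=n_redraws,
        seed=seed,
    )


def _subsample_accuracy(
    x: np.ndarray, is_male: np.ndarray, method: str, sink: list[float]
) -> bool:
    """Append the subsample's LOOCV sign-rule accuracy; False if degenerate."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            p_f, _ = _loocv_probabilities(x, is_male, method)
    except (np.linalg.LinAlgError, ValueError):
        return False
    correct = np.where(is_male, p_f < 0.5, p_f > 0.5)
    sink.append(float(correct.mean()))
    return True


# ---------------------------------------------------------------------------
# descriptive group comparison


@dataclass
class WelchResult:
    variable: str
    mean_f: float
    mean_m: float
    sd_f: float
    sd_m: float
    difference: float  # M - F
    ci_low: float
    ci_high: float
    confidence: float
    t: float
    df: float
    p_value: float


def welch_mean_difference(
    sample: ReferenceSample, variable: str, confidence: float = 0.90
) -> WelchResult:
    """Welch two-sample comparison of a measurement between the sexes.

    The difference is reported as male minus female with a
    Satterthwaite-df confidence interval at the requested level.
    """
    if variable not in sample.variables:
        raise ValueError(f"unknown variable {variable!r}")
    x = sample.matrix([variable])[:, 0]
    is_male = sample.sex_array() == MALE
    f, m = x[~is_male], x[is_male]
    if f.std(ddof=1) == 0 and m.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(m, f, equal_var=False)
    ci = res.confidence_interval(confidence)
    return WelchResult(
        variable=variable,
        mean_f=float(f.mean()),
        mean_m=float(m.mean()),
        sd_f=float(f.std(ddof=1)),
        sd_m=float(m.std(ddof=1)),
        difference=float(m.mean() - f.mean()),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        confidence=confidence,
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )
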