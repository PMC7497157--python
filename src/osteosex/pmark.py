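"""Bootstrap PMarks: additional discriminant-score cutoff points.

A classical discriminant cutoff marks only the 0.50 assignment
probability. A PMark at level p is the discriminant score at which the
plug-in posterior for a sex equals p, estimated as the mean over bootstrap
resamples of the reference sample (individuals resampled with
replacement, the discriminant refitted each time on the standardized
unit-within-variance score axis). Scores between the female and male
PMarks are reported as "probable" rather than definite, giving the
five-category scheme female / probable female / indeterminate / probable
male / male.

By default the score at posterior level p is obtained by exact analytic
inversion of the logistic-in-score posterior of each replicate's model;
an interpolation variant that brackets p between the posteriors of
observed individuals is available for comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logit

from .io import FEMALE, MALE, ReferenceSample
from .discriminant import (
    LinearDiscriminantModel,
    _fit_lda_core,
    _posterior_from_score,
)


@dataclass
class PMarkSet:
    """Symmetric score cutoffs at one posterior-probability level."""

    probability_level: float
    pmark_f: float  # negative score: at or below, call female at this level
    pmark_m: float  # positive score
    n_boot: int
    seed: int
    model_ref: str
    replicate_sd: float = float("nan")
    n_redraws: int = 0
    method: str = "analytic"
    per_replicate_scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "probability_level": self.probability_level,
            "pmark_f": self.pmark_f,
            "pmark_m": self.pmark_m,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "model_ref": self.model_ref,
            "replicate_sd": self.replicate_sd,
            "n_redraws": self.n_redraws,
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PMarkSet":
        return cls(**payload)


def write_pmarks(pmarks: Sequence[PMarkSet], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"pmarks": [p.to_dict() for p in pmarks]}, indent=2)
    )


def read_pmarks(path: str | Path) -> list[PMarkSet]:
    payload = json.loads(Path(path).read_text())
    return [PMarkSet.from_dict(d) for d in payload["pmarks"]]


def _bootstrap_models(
    sample: ReferenceSample,
    variables: Sequence[str],
    n_boot: int,
    rng: np.random.Generator,
    stratified: bool,
) -> tuple[list[tuple[float, float]], int]:
    """Fit the discriminant on ``n_boot`` resamples.

    Returns the per-replicate (score_mean_f, score_mean_m) pairs on each
    replicate's standardized axis, plus the degenerate-redraw count.
    Resampling is simple (unstratified) by default; draws leaving a sex
    with fewer than 2 distinct individuals, or a singular within-group
    covariance, are redrawn.
    """
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    n = len(x)
    idx_f = np.flatnonzero(~is_male)
    idx_m = np.flatnonzero(is_male)
    means: list[tuple[float, float]] = []
    n_redraws = 0
    max_redraws = 10 * n_boot
    while len(means) < n_boot:
        if stratified:
            idx = np.concatenate(
                [rng.choice(idx_f, size=len(idx_f)), rng.choice(idx_m, size=len(idx_m))]
            )
        else:
            idx = rng.integers(0, n, size=n)
        males = idx[is_male[idx]]
        females = idx[~is_male[idx]]
        if len(np.unique(males)) < 2 or len(np.unique(females)) < 2:
            n_redraws += 1
        else:
            try:
                _, _, mean_f, mean_m = _fit_lda_core(x[idx], is_male[idx], (0.5, 0.5))
            except (np.linalg.LinAlgError, ValueError):
                n_redraws += 1
            else:
                means.append((mean_f, mean_m))
                continue
        if n_redraws > max_redraws:
            raise RuntimeError(
                f"persistent degenerate resampling ({n_redraws} redraws); "
                "the sample is too small or too collinear to bootstrap"
            )
    return means, n_redraws


def _analytic_cutoff(mean_f: float, mean_m: float, p: float, sex: str) -> float:
    """Score where the equal-prior plug-in posterior for ``sex`` equals p."""
    separation = mean_m - mean_f
    const = (mean_f**2 - mean_m**2) / 2.0
    target = logit(p) if sex == MALE else -logit(p)
    return (target - const) / separation


def _interpolated_cutoff(
    scores: np.ndarray, p_m: np.ndarray, p: float, sex: str
) -> float:
    """Score where p is crossed, interpolating between observed individuals.

    NaN when no pair of individuals brackets the level.
    """
    order = np.argsort(p_m)
    pm_sorted, sc_sorted = p_m[order], scores[order]
    target = p if sex == MALE else 1.0 - p
    if target < pm_sorted[0] or target > pm_sorted[-1]:
        return float("nan")
    return float(np.interp(target, pm_sorted, sc_sorted))


def multilevel_pmarks(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    levels: Sequence[float] = (0.8, 0.9, 0.95),
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "analytic",
    stratified: bool = False,
    keep_replicates: bool = False,
) -> list[PMarkSet]:
    """PMark sets at several posterior levels on shared bootstrap replicates.

    Sharing the resamples across levels guarantees the nesting
    |PMark(0.8)| < |PMark(0.9)| < |PMark(0.95)| exactly, not merely in
    expectation.
    """
    variables = list(variables) if variables is not None else list(sample.variables)
    for p in levels:
        if not 0.5 < p < 1.0:
            raise ValueError(f"probability level must lie in (0.5, 1), got {p}")
    if method not in ("analytic", "interpolate"):
        raise ValueError(f"method must be 'analytic' or 'interpolate', got {method!r}")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    rng = np.random.default_rng(seed)
    model_ref = "lda:" + "+".join(variables)

    if method == "interpolate":
        return _multilevel_interpolated(
            sample, variables, levels, n_boot, seed, rng, stratified,
            model_ref, keep_replicates,
        )

    means, n_redraws = _bootstrap_models(sample, variables, n_boot, rng, stratified)
    result = []
    for p in sorted(levels):
        cut_m = np.array([_analytic_cutoff(mf, mm, p, MALE) for mf, mm in means])
        cut_f = np.array([_analytic_cutoff(mf, mm, p, FEMALE) for mf, mm in means])
        result.append(
            PMarkSet(
                probability_level=p,
                pmark_f=float(cut_f.mean()),
                pmark_m=float(cut_m.mean()),
                n_boot=n_boot,
                seed=seed,
                model_ref=model_ref,
                replicate_sd=float(cut_m.std(ddof=1)) if n_boot > 1 else float("nan"),
                n_redraws=n_redraws,
                method=method,
                per_replicate_scores=cut_m if keep_replicates else None,
            )
        )
    return result


def _multilevel_interpolated(
    sample, variables, levels, n_boot, seed, rng, stratified, model_ref,
    keep_replicates,
):
    """Interpolation variant: replicate scores of resampled individuals
    bracket the level; replicates with no bracket are dropped (NaN)."""
    x = sample.matrix(variables)
    is_male = sample.sex_array() == MALE
    n = len(x)
    idx_f = np.flatnonzero(~is_male)
    idx_m = np.flatnonzero(is_male)
    cuts = {p: ([], []) for p in levels}  # p -> (female cuts, male cuts)
    n_redraws = 0
    max_redraws = 10 * n_boot
    done = 0
    while done < n_boot:
        if stratified:
            idx = np.concatenate(
                [rng.choice(idx_f, size=len(idx_f)), rng.choice(idx_m, size=len(idx_m))]
            )
        else:
            idx = rng.integers(0, n, size=n)
        males = idx[is_male[idx]]
        females = idx[~is_male[idx]]
        if len(np.unique(males)) < 2 or len(np.unique(females)) < 2:
            n_redraws += 1
        else:
            try:
                b, b0, mean_f, mean_m = _fit_lda_core(x[idx], is_male[idx], (0.5, 0.5))
            except (np.linalg.LinAlgError, ValueError):
                n_redraws += 1
            else:
                scores = x[idx] @ b + b0
                _, p_m = _posterior_from_score(scores, mean_f, mean_m, (0.5, 0.5))
                for p in levels:
                    cuts[p][0].append(_interpolated_cutoff(scores, p_m, p, FEMALE))
                    cuts[p][1].append(_interpolated_cutoff(scores, p_m, p, MALE))
                done += 1
                continue
        if n_redraws > max_redraws:
            raise RuntimeError("persistent degenerate resampling")
    result = []
    for p in sorted(levels):
        cf = np.asarray(cuts[p][0])
        cm = np.asarray(cuts[p][1])
        result.append(
            PMarkSet(
                probability_level=p,
                pmark_f=float(np.nanmean(cf)),
                pmark_m=float(np.nanmean(cm)),
                n_boot=n_boot,
                seed=seed,
                model_ref=model_ref,
                replicate_sd=float(np.nanstd(cm, ddof=1)),
                n_redraws=n_redraws,
                method="interpolate",
                per_replicate_scores=cm if keep_replicates else None,
            )
        )
    return result


def compute_pmarks(
    sample: ReferenceSample,
    variables: Sequence[str] | None = None,
    p: float = 0.8,
    n_boot: int = 1000,
    seed: int | None = None,
    method: str = "analytic",
    stratified: bool = False,
    keep_replicates: bool = False,
) -> PMarkSet:
    """Bootstrap PMark pair at a single posterior-probability level."""
    (result,) = multilevel_pmarks(
        sample, variables, levels=(p,), n_boot=n_boot, seed=seed,
        method=method, stratified=stratified, keep_replicates=keep_replicates,
    )
    return result


def classify_with_pmarks(score: float, pmarks: PMarkSet) -> str:
    """Five-category sex call from a discriminant score.

    At or beyond a PMark the call is definite; between a PMark and the
    sectioning point it is "probable"; exactly at 0 it is indeterminate.
    Boundary scores take the stronger category.
    """
    if score <= pmarks.pmark_f:
        return FEMALE
    if score < 0:
        return "probable F"
    if score == 0:
        return "indeterminate"
    if score < pmarks.pmark_m:
        return "probable M"
    return MALE


def plot_score_densities(
    sample: ReferenceSample,
    model: LinearDiscriminantModel,
    pmark_sets: Sequence[PMarkSet],
    path: str | Path,
) -> None:
    """Per-sex discriminant-score density plot with the classical cutoff
    and each PMark pair as vertical lines, written to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    x = sample.matrix(model.variables)
    scores = x @ model.coefficient_vector() + model.intercept
    is_male = sample.sex_array() == MALE
    grid = np.linspace(scores.min() - 1.5, scores.max() + 1.5, 400)
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, mask, color in ((FEMALE, ~is_male, "#c44"), (MALE, is_male, "#46a")):
        kde = gaussian_kde(scores[mask])
        ax.plot(grid, kde(grid), color=color, label=label)
        ax.fill_between(grid, kde(grid), alpha=0.15, color=color)
    ax.axvline(0.0, color="black", lw=1.5, label="cutoff (0.50)")
    styles = [":", "--", "-."]
    for k, ps in enumerate(sorted(pmark_sets, key=lambda s: s.probability_level)):
        style = styles[k % len(styles)]
        ax.axvline(ps.pmark_f, color="gray", ls=style,
                   label=f"{ps.probability_level:.2f} PMarks")
        ax.axvline(ps.pmark_m, color="gray", ls=style)
    ax.set_xlabel("discriminant score")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
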