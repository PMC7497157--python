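# Methods

## Models

**Linear discriminant.** Two groups (F, M), score
`D = b0 + b·x`. The direction is `Σw⁻¹(μM − μF)` with the pooled
within-group covariance `Σw` computed with denominator `nF + nM − 2`. Two
conventions are fixed rather than left to the user, because the PMark
procedure averages scores across bootstrap refits and is only meaningful
on a shared scale:

- *scaling*: the pooled within-group variance of `D` is exactly 1;
- *centring*: `b0 = −b·(μF + μM)/2`, so the midpoint of the group score
  means is the score 0 and, at equal priors, the classical sectioning
  point is exactly 0 with female scores negative and male positive.

Posteriors are plug-in: each group's score density is taken as normal
with unit variance at its group score mean, combined with the priors by
Bayes' rule. At equal priors this makes `P(M|D)` logistic in `D` with
slope equal to the group-mean separation `δ` (the Mahalanobis distance
between centroids), which supplies closed forms used throughout: the
score at posterior level `p` is `ln(p/(1−p))/δ` plus a prior/asymmetry
offset, computed exactly, never searched. Priors default to equal
("uninformative"); proportional or explicit priors shift the even-odds
point, which is then computed from the inversion formula, not assumed at
0. A condition-number guard (1e12) raises on collinear variables; there
is no automatic regularization.

**Logistic regression.** Sex on measurements, female coded 1 by default
so the fitted equation reads as `P(F)`; the coding is stored in the model
file and flipping it negates all parameters. Fitting is Newton–Raphson
on the exact likelihood: convergence when the largest step is below 1e−8
or the log-likelihood change is below 1e−10 relative, capped at 100
iterations. Near-separation — realistic for strongly dimorphic skeletal
measurements — is flagged rather than fatal: when any fitted |linear
predictor| exceeds 30 the model is returned with `converged = False` and
a `SeparationWarning`; its sign-rule classifications remain usable, its
coefficient magnitudes do not. A singular Hessian falls back to a
pseudoinverse step so augmented diagnostic designs (see Box–Tidwell
below) degrade gracefully. AIC counts the intercept as a parameter
(`AIC = 2k − 2·LogLik` with `k` = coefficients + intercept). No
regularization; maximum likelihood only.

## Evaluation

**LOOCV** refits on `n−1` records per fold and predicts the held-out
individual; it is deterministic and permutation-invariant. Accuracy at a
decision probability `d ∈ [0.5, 1)` counts only individuals whose winning
probability reaches `d`; the rest are indeterminate. At `d = 0.5` the
rule reduces to the sign of the score (an exact tie is indeterminate, a
measure-zero event). Sub-threshold accuracy applies the 0.5 sign rule to
the complementary group (winning probability `< 0.8` by default); an
empty subset yields a defined not-applicable result. Retained plus
sub-threshold individuals partition the sample.

**B and Q indices** are computed on the cross-validated `P(F)` with
`Y = 1` for females. `B = 1 − mean((P−Y)²)`; chance predictions at
`P = 0.5` give `B = 0.75` — that is a property of the quadratic rule, and
the formula is implemented as printed. `Q = mean(1 + log2 P(true sex))`,
with probabilities clamped to `[1e−15, 1−1e−15]` so a single
(near-)separated fold yields a very negative, finite contribution rather
than `−inf`; both indices are invariant to swapping the class coding.

**Sample-size experiment.** Subsamples of sizes 10…n are drawn with
replacement; draws leaving a sex with fewer than two *distinct*
individuals (or a singular fit) are redrawn and counted. Each subsample
is scored by LOOCV *within itself* at decision probability 0.5 — the
self-contained reading of "accuracy under varying sample size"; an
alternative (evaluating against the full sample) would mix training and
test pools and is not offered. Default 100 replicates per size
stabilizes the mean; the acceptance script uses 10 per size, which keeps
the whole run at a few seconds while leaving the mean within a fraction
of a point of the 100-replicate value.

**Welch comparison.** Group difference reported as M − F with a
Satterthwaite-df CI (90 % default), via `scipy.stats.ttest_ind
(equal_var=False)`.

## PMarks

At each of `n_boot` (default 1000) bootstrap resamples — simple
unstratified resampling of individuals, with degenerate draws redrawn
and logged; a stratified option exists — the discriminant is refitted
under the standardized scaling and the score at posterior level `p` is
obtained by analytic inversion of that replicate's posterior. The PMark
pair is the mean of these scores; the replicate SD is reported as the
spread. The phrase "the score of an individual whose posterior is p" is
not literally implementable (no individual lands exactly at `p`), so
inversion is the default; an interpolation variant that brackets `p`
between the posteriors of observed individuals is available
(`method="interpolate"`) and agrees with the analytic route on large
samples but drops replicates in which no individual pair brackets the
level. Multiple levels share one set of resamples, which makes the
nesting `|PMark(0.8)| < |PMark(0.9)| < |PMark(0.95)|` exact rather than
merely expected, with level ratios equal to the log-odds ratios
`ln 9/ln 4`, `ln 19/ln 4`. Seeds are mandatory in the CLI and recorded in
every `PMarkSet`. Because the bootstrap averages `1/δ` over replicates
and `E[1/δ] > 1/E[δ]`, bootstrap PMarks sit slightly outside the
full-sample analytic inversion — both are available, and a test checks
they agree within the replicate spread. PMarks are defined for the
discriminant only; logistic probabilities need no cutoff machinery.

Five-category classification: score ≤ PMark_F → F; between PMark_F and
0 → probable F; exactly 0 → indeterminate; between 0 and PMark_M →
probable M; ≥ PMark_M → M. Boundaries go to the stronger category.

## Assumption diagnostics

- **VIF**: `1/(1−R²)` from regressing each variable on the others,
  sexes pooled; own OLS implementation, cross-checked against
  statsmodels in the tests.
- **Box's M**: `(n−k)ln|Sp| − Σ(ng−1)ln|Sg|` with Box's scaling constant
  and the χ² approximation, `df = (k−1)p(p+1)/2` (the χ², not F, form).
  No installed package provides it, so it is implemented directly and
  verified against step-by-step textbook arithmetic.
- **Mahalanobis outliers**: classical (non-robust) squared distances
  against the χ²_p 0.975 quantile, computed both pooled (whole-sample
  mean/covariance) and within each sex; both lists are reported because
  the two baselines flag different individuals in dimorphic data. A
  robust (MCD-style) variant is deliberately not offered.
- **Box–Tidwell logit-linearity**: one augmented logistic model with all
  main effects plus every `x·ln(x)` term jointly (one-at-a-time mode
  available); Wald z and p per interaction term. `x·ln(x)` is nearly
  collinear with `x` for large measurements, so this design is the main
  client of the pseudoinverse fallback; separation in the augmented model
  is flagged in the result.

## Synthetic data

`default_population()` emulates the reference collection the toolkit is
designed around: per-sex multivariate normal measurements with the
collection's published per-sex means and SDs for maximum humeral length,
head diameter and epicondylar breadth, 48 females / 36 males. The
inter-measurement correlation is not published; 0.5 is used for all
pairs — a moderate value consistent with the collection's reported VIFs
of 1.4–1.7 — and is configurable. Optional ages are truncated normals on
[19, 84] with the collection's per-sex age moments; no operation uses
them. `generate_known_model_sample` draws data for which a stated
discriminant truth (per-sex Gaussians, shared covariance) or logistic
truth (Gaussian covariates, Bernoulli sex) is exactly correct, together
with the analytic quantities (separation, population PMarks) that
recovery tests target; this parameter-recovery loop is the package's
primary self-test.

What the generator does *not* emulate: non-normality and skew (real
female humeral measurements in the reference collection violate
multivariate normality), measurement error, left/right substitution
effects, and the collection's true correlation structure. Passing tests
on synthetic data therefore demonstrate correctness of the estimators
and procedures, not the specific accuracy figures achievable on any real
collection; on the synthetic study conditions the pipeline lands close
to, but not exactly at, the collection's published accuracy and PMark
values, with the gap driven mostly by the assumed correlation.

## Numerical choices and edge cases

- Model JSON files carry full double precision (repr round-trip);
  published rounded coefficients are a user's deliberate input, never a
  serialization artifact. CSVs are written with repr-formatted floats
  and read with round-trip float parsing, so I/O cycles are value-exact.
- Listwise deletion over the selected variables only; no imputation.
  All measurements are assumed mm; no unit conversion.
- Sex parsing accepts f/female/0 and m/male/1 (case-insensitive);
  reference samples must be fully labeled, with at least two records per
  sex and unique ids.
- Degenerate bootstrap/subsample draws are redrawn with a cap (10× the
  replicate count) and a counted log, then a hard error.
- Decision probabilities live in `[0.5, 1)`; PMark levels in `(0.5, 1)`.

## Known limitations

- Two groups only; no QDA, nearest-neighbour discriminants, probit
  links, ordinal traits, or stepwise variable selection.
- PMark confidence is summarized by the replicate SD only.
- The bootstrap-vs-analytic choice for published PMark values is
  population-dependent; both are exposed so users can report either.
- Multivariate normality testing is out of scope; users should check it
  with dedicated tools before leaning on the LDA posterior.
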