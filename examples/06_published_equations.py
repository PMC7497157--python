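"""Apply published sex-estimation equations without the original data.

Coefficients published for a humeral discriminant function and logistic
regression are wrapped in model files and applied to new measurements.
The logistic equation yields probabilities directly; the discriminant
score alone supports only the dichotomous sign rule unless the authors
also published posterior machinery or PMarks.
"""

from osteosex import discriminant_score, predict_prob
from osteosex.io import ModelFile
from osteosex.logistic import LogisticModel

VARS = ["head_diameter", "epicondylar_breadth"]

ldf = ModelFile(
    model_kind="lda", variables=VARS,
    coefficients={"head_diameter": 0.3381, "epicondylar_breadth": 0.06205},
    intercept=-19.07,
)
logr = LogisticModel(
    variables=VARS,
    coefficients={"head_diameter": -0.8329, "epicondylar_breadth": -0.09285},
    intercept=43.42, coded_one_sex="F",
    log_likelihood=-14.93, aic=35.87, n=84, converged=True, iterations=5,
)

for label, meas in (("female-average", {"head_diameter": 41.62, "epicondylar_breadth": 55.31}),
                    ("male-average", {"head_diameter": 49.34, "epicondylar_breadth": 63.75}),
                    ("intermediate", {"head_diameter": 45.5, "epicondylar_breadth": 59.5})):
    d = discriminant_score(ldf, meas)
    p_f, p_m = predict_prob(logr, meas)
    sign_call = "F" if d < 0 else "M"
    print(f"{label}: D = {d:+.3f} (sign rule: {sign_call}),"
          f" logistic P(F) = {p_f:.4f}")
print("\nThe intermediate case shows the problem with dichotomous cutoffs:"
      " the sign rule must pick a sex even when the probability is near 0.5.")
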