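import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteosex import (
    classify_lda,
    discriminant_score,
    fit_lda,
    lda_posterior,
    score_cutoff_at_probability,
    write_reference_csv,
)
from osteosex.discriminant import LinearDiscriminantModel
from osteosex.io import ModelFile
from tests.conftest import make_sample

# published two-variable humeral discriminant (head diameter, epicondylar
# breadth in mm) used throughout as a loaded equation
LDF4 = ModelFile(
    model_kind="lda",
    variables=["head_diameter", "epicondylar_breadth"],
    coefficients={"head_diameter": 0.3381, "epicondylar_breadth": 0.06205},
    intercept=-19.07,
)


def symmetric_model(half_sep):
    return LinearDiscriminantModel(
        variables=["x"], coefficients={"x": 1.0}, intercept=0.0,
        score_mean_f=-half_sep, score_mean_m=half_sep,
        priors=(0.5, 0.5), n_f=10, n_m=10,
    )


class TestFit:
    def test_1d_toy_cutoff_at_raw_midpoint(self, toy_1d):
        model = fit_lda(toy_1d)
        # group means 2 and 7: score is 0 exactly at the midpoint 4.5
        assert discriminant_score(model, {"x": 4.5}) == pytest.approx(0.0, abs=1e-12)
        assert model.score_mean_m > 0 > model.score_mean_f
        assert model.score_mean_f == pytest.approx(-model.score_mean_m)

    def test_unit_within_group_score_variance(self, study_sample, humeral_variables):
        model = fit_lda(study_sample, humeral_variables)
        b = model.coefficient_vector()
        x = study_sample.matrix(humeral_variables)
        is_male = study_sample.sex_array() == "M"
        scores = x @ b
        ss = sum(
            float(np.sum((scores[g] - scores[g].mean()) ** 2))
            for g in (is_male, ~is_male)
        )
        assert ss / (len(x) - 2) == pytest.approx(1.0, rel=1e-10)

    def test_two_variable_toy_matches_pooled_covariance_oracle(self):
        # 8-point toy; oracle: explicit pooled-covariance matrix arithmetic
        f = np.array([[40.0, 54.0], [42.0, 56.0], [41.0, 57.0], [43.0, 55.0]])
        m = np.array([[48.0, 62.0], [50.0, 64.0], [49.0, 65.0], [51.0, 63.0]])
        sample = make_sample(f, m, variables=("u", "v"))
        model = fit_lda(sample, ["u", "v"])

        mu_f, mu_m = f.mean(axis=0), m.mean(axis=0)
        sw = ((f - mu_f).T @ (f - mu_f) + (m - mu_m).T @ (m - mu_m)) / (8 - 2)
        direction = np.linalg.inv(sw) @ (mu_m - mu_f)
        fitted = model.coefficient_vector()
        # equal up to the positive standardizing scale
        ratio = fitted / direction
        assert ratio[0] == pytest.approx(ratio[1], rel=1e-10)
        assert ratio[0] > 0
        # intercept centres the midpoint of the centroids at score 0
        assert model.intercept == pytest.approx(
            -float(fitted @ (mu_f + mu_m) / 2), rel=1e-10
        )

    def test_collinear_variables_raise(self):
        f = [[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]
        m = [[5.0, 10.0], [6.0, 12.0], [7.0, 14.0]]
        sample = make_sample(f, m, variables=("u", "v"))
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(sample)

    def test_fewer_than_two_per_sex_raises(self):
        with pytest.raises(ValueError):
            make_sample([[1.0]], [[5.0], [6.0]])

    @pytest.mark.parametrize("k", [0.1, 10.0, 250.0])
    def test_affine_equivariance_of_scores(self, study_sample, humeral_variables, k):
        # rescaling one input variable rescales its coefficient by 1/k and
        # leaves every individual's score unchanged
        base = fit_lda(study_sample, humeral_variables)
        scaled_records2 = make_sample(
            study_sample.matrix(humeral_variables)[study_sample.sex_array() == "F"]
            * np.array([k, 1.0]),
            study_sample.matrix(humeral_variables)[study_sample.sex_array() == "M"]
            * np.array([k, 1.0]),
            variables=humeral_variables,
        )
        scaled2 = fit_lda(scaled_records2, humeral_variables)
        assert scaled2.coefficients["head_diameter"] == pytest.approx(
            base.coefficients["head_diameter"] / k, rel=1e-9
        )
        x0 = study_sample.records[0].measurements
        x0_scaled = {"head_diameter": x0["head_diameter"] * k,
                     "epicondylar_breadth": x0["epicondylar_breadth"]}
        assert discriminant_score(scaled2, x0_scaled) == pytest.approx(
            discriminant_score(base, x0), rel=1e-9
        )

    def test_matches_reference_r_implementation(self, tmp_path, study_sample,
                                                humeral_variables):
        # independent oracle: MASS::lda with plug-in posteriors in R
        csv = tmp_path / "sample.csv"
        write_reference_csv(study_sample, csv)
        script = tmp_path / "lda.R"
        script.write_text(
            "suppressMessages(library(MASS))\n"
            f"d <- read.csv('{csv}')\n"
            "fit <- lda(sex ~ head_diameter + epicondylar_breadth, data = d,"
            " prior = c(0.5, 0.5))\n"
            "post <- predict(fit, method = 'plug-in')$posterior\n"
            "cat(sprintf('%.12f\\n', post[, 'M']))\n"
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        r_post_m = np.array([float(v) for v in proc.stdout.split()])
        model = fit_lda(study_sample, humeral_variables)
        b = model.coefficient_vector()
        scores = study_sample.matrix(humeral_variables) @ b + model.intercept
        ours = np.array([lda_posterior(model, s)[1] for s in scores])
        np.testing.assert_allclose(ours, r_post_m, atol=1e-8)


class TestScore:
    def test_zero_coefficients_return_intercept(self):
        mf = ModelFile(model_kind="lda", variables=["x"],
                       coefficients={"x": 0.0}, intercept=3.25)
        assert discriminant_score(mf, {"x": 123.0}) == 3.25

    def test_missing_variable_named_in_error(self):
        with pytest.raises(ValueError, match="epicondylar_breadth"):
            discriminant_score(LDF4, {"head_diameter": 45.0})

    def test_published_equation_at_group_means(self):
        # hand arithmetic on the published coefficients at the published
        # per-sex measurement means
        female = discriminant_score(
            LDF4, {"head_diameter": 41.62, "epicondylar_breadth": 55.31}
        )
        male = discriminant_score(
            LDF4, {"head_diameter": 49.34, "epicondylar_breadth": 63.75}
        )
        assert female == pytest.approx(-1.5663, abs=2e-3)
        assert male == pytest.approx(1.5675, abs=2e-3)


class TestPosterior:
    def test_midpoint_is_even_odds(self):
        model = symmetric_model(1.5)
        assert lda_posterior(model, 0.0) == pytest.approx((0.5, 0.5))

    @given(st.floats(-6, 6))
    @settings(max_examples=50, deadline=None)
    def test_mirror_symmetry_under_equal_priors(self, d):
        model = symmetric_model(1.2)
        p_f_pos, p_m_pos = lda_posterior(model, d)
        p_f_neg, p_m_neg = lda_posterior(model, -d)
        assert p_m_pos == pytest.approx(p_f_neg, abs=1e-12)
        assert p_f_pos + p_m_pos == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_logistic_in_score(self):
        # score means +-1.54 (separation 3.08): P_M(0.45) = 1/(1+e^-1.386)
        model = symmetric_model(1.54)
        _, p_m = lda_posterior(model, 0.45)
        assert p_m == pytest.approx(1.0 / (1.0 + math.exp(-3.08 * 0.45)), abs=1e-12)
        assert p_m == pytest.approx(0.80, abs=5e-3)

    def test_posterior_monotone_in_score(self):
        model = symmetric_model(1.0)
        grid = np.linspace(-5, 5, 101)
        p_m = np.array([lda_posterior(model, d)[1] for d in grid])
        assert np.all(np.diff(p_m) > 0)

    def test_unequal_priors_shift_the_even_odds_point(self):
        model = LinearDiscriminantModel(
            variables=["x"], coefficients={"x": 1.0}, intercept=0.0,
            score_mean_f=-1.0, score_mean_m=1.0, priors=(0.8, 0.2),
            n_f=10, n_m=10,
        )
        _, p_m_at_zero = lda_posterior(model, 0.0)
        assert p_m_at_zero < 0.5
        cut = score_cutoff_at_probability(model, 0.5, "M")
        assert cut > 0
        assert lda_posterior(model, cut)[1] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("p", [0.6, 0.8, 0.9, 0.95])
    def test_cutoff_inversion_closed_form(self, p):
        model = symmetric_model(1.54)
        cut = score_cutoff_at_probability(model, p, "M")
        assert cut == pytest.approx(math.log(p / (1 - p)) / 3.08, rel=1e-12)
        # and the female cutoff mirrors it
        assert score_cutoff_at_probability(model, p, "F") == pytest.approx(-cut)


class TestClassify:
    def test_sign_rule_at_default_decision(self):
        model = symmetric_model(1.5)
        # score -0.01: barely female side
        call = classify_lda(model, {"x": -0.01 / 1.0})
        assert call.label == "F"
        assert classify_lda(model, {"x": 0.01}).label == "M"

    def test_below_decision_probability_is_indeterminate(self):
        model = symmetric_model(1.54)
        # D = 0.4 gives P_M about 0.77 < 0.8
        call = classify_lda(model, {"x": 0.4}, decision_probability=0.8)
        assert call.label == "indeterminate"
        assert call.probability < 0.8

    def test_decision_probability_domain(self):
        model = symmetric_model(1.0)
        for bad in (0.49, 1.0, 1.5):
            with pytest.raises(ValueError):
                classify_lda(model, {"x": 1.0}, decision_probability=bad)

    def test_raising_decision_probability_never_flips_a_call(self, study_sample,
                                                             humeral_variables):
        model = fit_lda(study_sample, humeral_variables)
        for record in study_sample.records[:20]:
            lo = classify_lda(model, record.measurements, 0.5)
            hi = classify_lda(model, record.measurements, 0.9)
            if hi.label != "indeterminate":
                assert hi.label == lo.label
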