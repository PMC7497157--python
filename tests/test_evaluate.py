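import math

import numpy as np
import pytest
from scipy import stats

from osteosex import (
    brier_index,
    loocv,
    q_index,
    sample_size_experiment,
    subthreshold_accuracy,
    welch_mean_difference,
)
from osteosex.evaluate import EvaluationReport, IndividualResult, AccuracySummary
from osteosex.synthgen import LdaTruth, generate_known_model_sample
from tests.conftest import make_sample


def report_from_probs(probs_f, true_sexes):
    """Minimal report carrying given LOOCV P(F) values."""
    per = [
        IndividualResult(id=str(k), true_sex=s, p_f=p, p_m=1 - p, labels={})
        for k, (p, s) in enumerate(zip(probs_f, true_sexes))
    ]
    y = [1 if s == "F" else 0 for s in true_sexes]
    return EvaluationReport(
        method="lda", variables=["x"], decision_probabilities=[],
        per_individual=per, accuracy={}, b=brier_index(probs_f, y),
        q=q_index(probs_f, y),
    )


class TestScoringRules:
    def test_perfect_prediction(self):
        assert brier_index([1, 0, 1], [1, 0, 1]) == 1.0
        assert q_index([1, 0, 1], [1, 0, 1]) == pytest.approx(1.0)

    def test_uniform_chance(self):
        p = [0.5] * 8
        y = [1, 0, 1, 0, 1, 1, 0, 0]
        assert brier_index(p, y) == pytest.approx(0.75)
        assert q_index(p, y) == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_chance_is_negative_q(self):
        assert q_index([0.05, 0.9], [1, 0]) < 0

    def test_hand_computed_mixed_case(self):
        # B = 1 - ((0.9-1)^2 + (0.3-0)^2)/2 = 0.95
        assert brier_index([0.9, 0.3], [1, 0]) == pytest.approx(0.95)
        # Q = (1+log2(0.9) + 1+log2(0.7))/2
        expected = (2 + math.log2(0.9) + math.log2(0.7)) / 2
        assert q_index([0.9, 0.3], [1, 0]) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            brier_index([0.5], [1, 0])
        with pytest.raises(ValueError, match="length"):
            q_index([0.5], [1, 0])

    def test_clamping_keeps_q_finite(self):
        assert math.isfinite(q_index([0.0, 1.0], [1, 0]))

    def test_coding_swap_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.01, 0.99, 30)
        y = rng.integers(0, 2, 30)
        assert brier_index(p, y) == pytest.approx(brier_index(1 - p, 1 - y))
        assert q_index(p, y) == pytest.approx(q_index(1 - p, 1 - y))


@pytest.fixture(scope="module")
def overlap_sample():
    truth = LdaTruth(
        variables=["u", "v"],
        mean_f=[40.0, 55.0], mean_m=[44.0, 59.0],
        covariance=[[6.0, 2.0], [2.0, 9.0]],
    )
    sample, _ = generate_known_model_sample(truth, n=20, seed=11)
    return sample


class TestLoocv:
    @pytest.mark.parametrize("method", ["lda", "logr"])
    def test_matches_naive_refit_loop(self, overlap_sample, method):
        """Fold-by-fold equality with an externally coded hold-one-out loop
        built from the public fitting functions."""
        import warnings
        from osteosex import fit_lda, fit_logr, lda_posterior, discriminant_score
        from osteosex.logistic import SeparationWarning, predict_prob

        report = loocv(overlap_sample, method, decision_probabilities=(0.5, 0.8))
        for i, record in enumerate(overlap_sample.records):
            rest = overlap_sample.drop_index(i)
            if method == "lda":
                m = fit_lda(rest)
                p_f = lda_posterior(m, discriminant_score(m, record.measurements))[0]
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SeparationWarning)
                    m = fit_logr(rest)
                p_f = predict_prob(m, record.measurements)[0]
            assert report.per_individual[i].p_f == pytest.approx(p_f, abs=1e-10)

    @pytest.mark.parametrize("method", ["lda", "logr"])
    def test_separated_data_classified_perfectly(self, method):
        sample = make_sample(
            [[10.0], [11.0], [12.0], [13.0]], [[30.0], [31.0], [32.0], [33.0]]
        )
        report = loocv(sample, method, decision_probabilities=(0.5,))
        assert report.accuracy[0.5].overall == 1.0
        if method == "logr":
            assert report.n_separated_folds == len(sample)

    def test_permutation_invariance(self, overlap_sample):
        report = loocv(overlap_sample, "lda")
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(overlap_sample))
        shuffled = overlap_sample.subset(perm)
        report2 = loocv(shuffled, "lda")
        by_id = {r.id: r.p_f for r in report.per_individual}
        for r in report2.per_individual:
            assert r.p_f == pytest.approx(by_id[r.id], abs=1e-12)

    def test_retained_n_monotone_in_decision_probability(self, overlap_sample):
        report = loocv(overlap_sample, "lda", decision_probabilities=(0.5, 0.8, 0.95))
        retained = [report.accuracy[dp].retained_n for dp in (0.5, 0.8, 0.95)]
        assert retained[0] >= retained[1] >= retained[2]
        assert retained[0] == len(overlap_sample)

    def test_accuracy_is_correct_over_retained(self, overlap_sample):
        report = loocv(overlap_sample, "lda", decision_probabilities=(0.8,))
        acc = report.accuracy[0.8]
        correct = sum(
            1 for r in report.per_individual
            if r.labels[0.8] == r.true_sex
        )
        assert acc.overall == pytest.approx(correct / acc.retained_n)

    def test_retained_plus_subthreshold_partition(self, overlap_sample):
        report = loocv(overlap_sample, "lda", decision_probabilities=(0.8,))
        sub = subthreshold_accuracy(report, 0.8)
        assert report.accuracy[0.8].retained_n + sub.n == len(overlap_sample)


class TestSubthreshold:
    def test_not_applicable_when_all_confident(self):
        rep = report_from_probs([0.99, 0.98, 0.01, 0.02], ["F", "F", "M", "M"])
        sub = subthreshold_accuracy(rep, 0.8)
        assert not sub.applicable
        assert sub.overall is None

    def test_two_correct_two_wrong_is_half(self):
        # all four below 0.8; sign rule right for the first two only
        rep = report_from_probs([0.7, 0.3, 0.6, 0.25], ["F", "M", "M", "F"])
        sub = subthreshold_accuracy(rep, 0.8)
        assert sub.n == 4
        assert sub.overall == pytest.approx(0.5)

    def test_per_sex_strata(self):
        rep = report_from_probs([0.7, 0.6, 0.3, 0.4], ["F", "F", "M", "F"])
        sub = subthreshold_accuracy(rep, 0.8)
        assert sub.female == pytest.approx(2 / 3)
        assert sub.male == pytest.approx(1.0)


class TestSampleSizeExperiment:
    def test_contract_and_determinism(self, overlap_sample):
        kwargs = dict(
            method="lda", sizes=[8, 10, 12], replicates_per_size=5, seed=42
        )
        res = sample_size_experiment(overlap_sample, **kwargs)
        assert res.sizes == [8, 10, 12]
        assert all(len(a) == 5 for a in res.accuracies)
        flat = [a for accs in res.accuracies for a in accs]
        assert all(0.0 <= a <= 1.0 for a in flat)
        res2 = sample_size_experiment(overlap_sample, **kwargs)
        assert res.accuracies == res2.accuracies
        assert res.overall_mean == res2.overall_mean

    def test_accuracy_trend_increases_with_size(self):
        # moderately dimorphic population: accuracy should climb with n
        truth = LdaTruth(
            variables=["x"], mean_f=[40.0], mean_m=[43.0], covariance=[[4.0]]
        )
        sample, _ = generate_known_model_sample(truth, n=120, seed=2)
        res = sample_size_experiment(
            sample, "lda", sizes=list(range(6, 61, 6)),
            replicates_per_size=10, seed=9,
        )
        rho = stats.spearmanr(res.sizes, res.mean_per_size).statistic
        assert rho > 0

    def test_size_below_minimum_rejected(self, overlap_sample):
        with pytest.raises(ValueError):
            sample_size_experiment(
                overlap_sample, "lda", sizes=[3], replicates_per_size=2, seed=1
            )


class TestWelch:
    def test_identical_groups(self):
        sample = make_sample([[1.0], [2.0], [3.0]], [[1.0], [2.0], [3.0]])
        res = welch_mean_difference(sample, "x")
        assert res.difference == 0.0
        assert res.ci_low < 0 < res.ci_high

    def test_hand_computed_welch_formula(self):
        f = np.array([10.0, 12.0, 14.0, 16.0])
        m = np.array([20.0, 21.0, 25.0])
        sample = make_sample(f[:, None], m[:, None])
        res = welch_mean_difference(sample, "x", confidence=0.90)
        vf, vm = f.var(ddof=1) / len(f), m.var(ddof=1) / len(m)
        t = (m.mean() - f.mean()) / math.sqrt(vf + vm)
        df = (vf + vm) ** 2 / (vf**2 / (len(f) - 1) + vm**2 / (len(m) - 1))
        half = stats.t.ppf(0.95, df) * math.sqrt(vf + vm)
        assert res.t == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.ci_low == pytest.approx(res.difference - half)
        assert res.ci_high == pytest.approx(res.difference + half)

    def test_zero_variance_both_groups_rejected(self):
        sample = make_sample([[5.0], [5.0]], [[7.0], [7.0]])
        with pytest.raises(ValueError, match="zero variance"):
            welch_mean_difference(sample, "x")

    def test_unknown_variable(self, overlap_sample):
        with pytest.raises(ValueError):
            welch_mean_difference(overlap_sample, "femur_length")
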