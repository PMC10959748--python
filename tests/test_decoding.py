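"""Linear-SVM decoding, shuffle correction, and weight distributions."""

import numpy as np
import pytest

from socoop import decoding as D
from socoop.config import AnalysisConfig
from socoop.stats import learning_trend
from socoop.synth import simulate_decode_observations

FAST = AnalysisConfig(svm_iterations=20)


class TestDecode:
    def test_separable_classes_hit_ceiling(self, rng):
        X, y = simulate_decode_observations(40, 20, 4.0, rng)
        res = D.decode(D.DecodeProblem(X, y), seed=1, config=FAST)
        assert res.mean_accuracy_actual > 97.0
        assert res.mean_accuracy_shuffled == pytest.approx(50.0, abs=4.0)
        assert res.shuffle_corrected > 45.0

    def test_label_independent_features_give_zero_corrected(self, rng):
        # averaged over independent null sessions the corrected accuracy
        # sits at 0 (|mean| < 3 points)
        vals = []
        for k in range(5):
            X, y = simulate_decode_observations(50, 25, 0.0, rng)
            res = D.decode(D.DecodeProblem(X, y), seed=k, config=FAST)
            vals.append(res.shuffle_corrected)
        assert abs(np.mean(vals)) < 3.0

    def test_accuracy_monotone_in_separation(self, rng):
        accs = []
        for sep in (0.0, 0.7, 3.0):
            X, y = simulate_decode_observations(40, 20, sep, rng)
            res = D.decode(D.DecodeProblem(X, y), seed=2, config=FAST)
            accs.append(res.mean_accuracy_actual)
        assert accs[0] < accs[1] < accs[2]

    def test_balancing_equalizes_class_counts(self, rng):
        y = np.r_[np.zeros(30), np.ones(70)].astype(int)
        idx = D._balance(y, rng)
        counts = np.bincount(y[idx])
        assert counts[0] == counts[1] == 30

    def test_corrected_is_actual_minus_shuffled(self, rng):
        X, y = simulate_decode_observations(30, 10, 1.0, rng)
        res = D.decode(D.DecodeProblem(X, y), seed=3, config=FAST)
        assert res.shuffle_corrected == pytest.approx(
            res.mean_accuracy_actual - res.mean_accuracy_shuffled)

    def test_reproducible_given_seed(self, rng):
        X, y = simulate_decode_observations(30, 10, 1.0, rng)
        r1 = D.decode(D.DecodeProblem(X, y), seed=9, config=FAST)
        r2 = D.decode(D.DecodeProblem(X, y), seed=9, config=FAST)
        assert r1.mean_accuracy_actual == r2.mean_accuracy_actual
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_fold_mean_weights_point_the_same_way(self, rng):
        X, y = simulate_decode_observations(40, 12, 2.0, rng)
        r1 = D.decode(D.DecodeProblem(X, y), seed=5, config=FAST)
        r2 = D.decode(D.DecodeProblem(X, y), seed=5, config=FAST,
                      weight_mode="fold_mean")
        cos = np.dot(r1.normalized_weights, r2.normalized_weights)
        assert cos > 0.9

    def test_train_accuracy_reported_for_overfitting_check(self, rng):
        X, y = simulate_decode_observations(30, 10, 0.0, rng)
        res = D.decode(D.DecodeProblem(X, y), seed=4, config=FAST)
        assert res.train_accuracy >= res.mean_accuracy_actual


class TestNormalizeWeights:
    def test_single_unit_is_plus_minus_one(self):
        assert D.normalize_weights([-2.5]).tolist() == [-1.0]

    def test_three_four_becomes_point_six_point_eight(self):
        np.testing.assert_allclose(D.normalize_weights([3.0, 4.0]),
                                   [0.6, 0.8])

    def test_scale_invariance(self, rng):
        w = rng.normal(size=12)
        np.testing.assert_allclose(D.normalize_weights(5.0 * w),
                                   D.normalize_weights(w))
        np.testing.assert_allclose(D.normalize_weights(-5.0 * w),
                                   -D.normalize_weights(w))

    def test_unit_norm_output(self, rng):
        w = D.normalize_weights(rng.normal(size=40))
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_zero_vector_signalled(self):
        with pytest.raises(ValueError):
            D.normalize_weights(np.zeros(5))


class TestWeightDistribution:
    def test_uniform_weights_zero_variance(self):
        n = 25
        w = np.full(n, 1 / np.sqrt(n))
        m = D.weight_distribution_metrics(w)
        assert m.variance == pytest.approx(0.0, abs=1e-12)

    def test_concentrated_weights_maximize_variance(self):
        n = 25
        concentrated = np.zeros(n)
        concentrated[0] = 1.0
        v_conc = D.weight_distribution_metrics(concentrated).variance
        v_unif = D.weight_distribution_metrics(
            np.full(n, 1 / np.sqrt(n))).variance
        assert v_conc > v_unif
        # among unit-norm vectors the single-spike vector is extremal
        for _ in range(20):
            w = D.normalize_weights(np.random.default_rng(_).normal(size=n))
            assert D.weight_distribution_metrics(w).variance <= v_conc + 1e-12

    def test_concentrating_to_distributed_gives_negative_trend(self, rng):
        # sessions move signal from 2 dominant units to the whole population
        n_units, weights = 24, []
        for s in range(10):
            informative = np.full(n_units, 0.15 + 0.08 * s)
            informative[:2] = 2.0 - 0.15 * s
            X, y = simulate_decode_observations(60, n_units, 1.0, rng,
                                                informative=informative)
            res = D.decode(D.DecodeProblem(X, y), seed=s,
                           config=AnalysisConfig(svm_iterations=1))
            weights.append(res.normalized_weights)
        trends = D.weight_metric_trends(weights)
        assert trends["variance"].slope < 0
        assert trends["variance"].regression_p < 0.05


class TestConditionalChoice:
    def test_identical_conditions_show_no_difference(self, rng):
        per_session = []
        for s in range(8):
            X, y = simulate_decode_observations(40, 15, 1.5, rng)
            mask = rng.random(len(y)) < 0.5
            per_session.append(D.conditional_choice_decode(
                X, y, mask, seed=s, config=FAST))
        res = D.compare_conditions(per_session)
        assert res["p"] > 0.05

    def test_cue_dependent_signal_detected(self, rng):
        # choice is decodable only in with-cue observations
        per_session = []
        for s in range(8):
            Xc, yc = simulate_decode_observations(30, 15, 2.5, rng)
            Xn, yn = simulate_decode_observations(30, 15, 0.0, rng)
            X = np.vstack([Xc, Xn])
            y = np.r_[yc, yn]
            mask = np.r_[np.ones(len(yc), bool), np.zeros(len(yn), bool)]
            per_session.append(D.conditional_choice_decode(
                X, y, mask, seed=s, config=FAST))
        res = D.compare_conditions(per_session)
        assert res["mean_with_cue"] > res["mean_without_cue"]
        assert res["p"] < 0.01

    def test_tiny_condition_skipped(self, rng):
        X, y = simulate_decode_observations(20, 10, 1.0, rng)
        mask = np.zeros(len(y), bool)
        mask[0] = True   # only one with-cue observation
        out = D.conditional_choice_decode(X, y, mask, seed=0, config=FAST)
        assert out["with_cue"] is None
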