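import numpy as np
import pytest
from scipy import optimize

import nirstate as ns
from conftest import random_feature_matrix


def fm(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return ns.FeatureMatrix(values=values, labels=list(labels), column_names=names)


class TestNormalizer:
    def test_hand_computed_mean_and_sd(self):
        stats = ns.fit_normalizer(fm([[0.0, 0.0], [2.0, 2.0]], ["relax", "nback"]))
        np.testing.assert_allclose(stats.mean, [1.0, 1.0])
        np.testing.assert_allclose(stats.sd, [np.sqrt(2.0), np.sqrt(2.0)])

    def test_self_application_standardizes(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 2.0, (30, 4))
        stats = ns.fit_normalizer(x)
        z = stats.apply(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_test_set_transformed_with_train_statistics(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0.0, 1.0, (20, 3))
        test = train + 5.0  # shifted distribution
        stats = ns.fit_normalizer(train)
        z = stats.apply(test)
        # were test statistics used, the mean would be ~0
        assert np.all(z.mean(axis=0) > 3.0)

    def test_zero_variance_column_named(self):
        m = fm([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]], ["a", "b", "a"],
               names=["const_col", "ok"])
        with pytest.raises(ValueError, match="const_col"):
            ns.fit_normalizer(m)


def hard_margin_oracle(x, y):
    """Brute-force dual QP for the hard-margin linear SVM on a tiny set.

    max sum(a) - 1/2 sum_ij a_i a_j y_i y_j <x_i, x_j>
    s.t. a >= 0, sum a_i y_i = 0; then w = sum a_i y_i x_i, margin = 2/||w||.
    """
    q = (y[:, None] * y[None, :]) * (x @ x.T)

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ q @ a)

    cons = {"type": "eq", "fun": lambda a: a @ y}
    res = optimize.minimize(
        neg_dual, np.ones(len(y)), bounds=[(0, None)] * len(y),
        constraints=[cons], method="SLSQP",
        options={"ftol": 1e-12, "maxiter": 500},
    )
    w = (res.x * y) @ x
    return 2.0 / np.linalg.norm(w)


class TestTrainClassifier:
    def test_separable_two_points_classified_correctly(self):
        m = fm([[-1.0, -1.0], [1.0, 1.0]], ["relax", "nback"])
        stats = ns.NormalizationStats(mean=np.zeros(2), sd=np.ones(2))
        model = ns.train_classifier(m, stats)
        assert model.predict(m) == ["relax", "nback"]

    def test_label_flip_negates_decision_scores(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(-1, 0.3, (5, 2)), rng.normal(1, 0.3, (5, 2))])
        labels = ["relax"] * 5 + ["nback"] * 5
        flipped = ["nback"] * 5 + ["relax"] * 5
        stats = ns.NormalizationStats(mean=np.zeros(2), sd=np.ones(2))
        m1, m2 = fm(x, labels), fm(x, flipped)
        s1 = ns.train_classifier(m1, stats).decision_scores(m1)
        s2 = ns.train_classifier(m2, stats).decision_scores(m2)
        np.testing.assert_allclose(s1, -s2, atol=1e-8)

    def test_margin_matches_dual_qp_oracle(self):
        # hand-built separable 4-point set; large C approximates hard margin
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 3.0], [1.0, 3.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        m = fm(x, ["nback", "nback", "relax", "relax"])
        stats = ns.NormalizationStats(mean=np.zeros(2), sd=np.ones(2))
        model = ns.train_classifier(m, stats, C=1e6)
        margin = 2.0 / np.linalg.norm(model.svm.coef_)
        assert margin == pytest.approx(hard_margin_oracle(x, y), rel=1e-4)
        assert margin == pytest.approx(3.0, rel=1e-4)  # geometric gap

    def test_single_class_rejected(self):
        m = fm([[0.0], [1.0]], ["relax", "relax"])
        with pytest.raises(ValueError, match="both classes"):
            ns.train_classifier(m)


class TestCrossvalidate:
    def test_perfectly_informative_features_reach_100(self):
        labels = ["relax", "nback"] * 10
        x = np.array([[1.0, 1.0] if l == "relax" else [-1.0, -1.0] for l in labels])
        x += np.random.default_rng(0).normal(0, 0.01, x.shape)
        cv = ns.crossvalidate(fm(x, labels), k=5, seed=0)
        assert cv.mean_accuracy == 100.0

    def test_folds_partition_epochs(self):
        rng = np.random.default_rng(3)
        m = random_feature_matrix(rng, n_epochs=20)
        cv = ns.crossvalidate(m, k=5, seed=1)
        assert sorted(set(cv.fold_assignment)) == [0, 1, 2, 3, 4]
        assert all(cv.fold_assignment.count(f) == 4 for f in range(5))
        assert len(cv.per_epoch_predictions) == 20
        assert sum(cv.confusion.values()) == 20

    def test_mean_accuracy_is_fold_mean(self):
        rng = np.random.default_rng(4)
        cv = ns.crossvalidate(random_feature_matrix(rng), k=5, seed=2)
        assert cv.mean_accuracy == pytest.approx(100 * np.mean(cv.fold_accuracies))

    def test_null_features_stay_within_chance_interval(self):
        # pure-noise features: fold-mean accuracy should fall inside the
        # adjusted-Wald interval around 50% in >= 90% of seeds
        bound = ns.chance_upper_bound(20, 2, 0.05)
        inside = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            cv = ns.crossvalidate(random_feature_matrix(rng), k=5, seed=seed)
            inside += bound.lower_bound <= cv.mean_accuracy <= bound.upper_bound
        assert inside >= 45

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(5)
        m = random_feature_matrix(rng)
        a = ns.crossvalidate(m, k=5, seed=9)
        b = ns.crossvalidate(m, k=5, seed=9)
        assert a.fold_assignment == b.fold_assignment
        assert a.fold_accuracies == b.fold_accuracies

    def test_k_larger_than_epochs_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            ns.crossvalidate(random_feature_matrix(rng, n_epochs=4), k=5)


class TestReplayOnline:
    def test_identity_replay_equals_resubstitution(self):
        rng = np.random.default_rng(7)
        m = random_feature_matrix(rng)
        model = ns.train_classifier(m)
        resub = 100 * np.mean(np.array(model.predict(m)) == np.array(m.labels))
        _preds, acc, _ = ns.replay_online(m, m)
        assert acc == pytest.approx(resub)

    def test_high_snr_online_beats_chance(self):
        bound = ns.chance_upper_bound(20, 2, 0.05)
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            labels = ["relax", "nback"] * 10
            mu = {"relax": 2.0, "nback": -2.0}
            draw = lambda: np.array(
                [rng.normal(mu[l], 0.5, 4) for l in labels]
            )
            calib = fm(draw(), labels)
            online = fm(draw(), labels)
            _p, acc, _ = ns.replay_online(calib, online)
            ok += acc >= bound.upper_bound
        assert ok >= 18

    def test_shuffled_labels_near_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            calib = random_feature_matrix(rng)
            online = random_feature_matrix(rng)
            rng.shuffle(online.labels)
            _p, acc, _ = ns.replay_online(calib, online)
            accs.append(acc)
        # 20 x 20 = 400 effective Bernoulli(0.5) trials
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        calib = random_feature_matrix(rng)
        online = random_feature_matrix(rng, n_features=5)
        with pytest.raises(ValueError, match="columns"):
            ns.replay_online(calib, online)


def test_no_leakage_from_test_fold():
    """Corrupting test-fold values must not change the fitted fold model."""
    rng = np.random.default_rng(9)
    m = random_feature_matrix(rng, n_epochs=20)
    cv = ns.crossvalidate(m, k=5, seed=0)
    for fold in range(5):
        test_idx = [i for i, f in enumerate(cv.fold_assignment) if f == fold]
        train_idx = [i for i, f in enumerate(cv.fold_assignment) if f != fold]
        train = ns.FeatureMatrix(
            values=m.values[train_idx],
            labels=[m.labels[i] for i in train_idx],
            column_names=m.column_names,
        )
        before = ns.train_classifier(train)
        corrupted = m.values.copy()
        corrupted[test_idx] = 1e6
        train_after = ns.FeatureMatrix(
            values=corrupted[train_idx],
            labels=[m.labels[i] for i in train_idx],
            column_names=m.column_names,
        )
        after = ns.train_classifier(train_after)
        np.testing.assert_array_equal(before.stats.mean, after.stats.mean)
        np.testing.assert_array_equal(before.stats.sd, after.stats.sd)
        np.testing.assert_array_equal(before.svm.coef_, after.svm.coef_)
        np.testing.assert_array_equal(before.svm.intercept_, after.svm.intercept_)
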