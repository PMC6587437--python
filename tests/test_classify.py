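"""LDA, KNN, cross-validation, performance metrics and RFE ranking."""

import numpy as np
import pytest

from commpat.classify import (
    FeatureTable, cross_validate, knn_predict, lda_fit, lda_predict,
    performance, rfe_rank, stratified_folds,
)


def table(x, y, names=None):
    x = np.asarray(x, dtype=float)
    names = names or [f"f{i}" for i in range(x.shape[1])]
    return FeatureTable(x, np.asarray(y), names)


class TestLdaFit:
    def test_hand_pooled_variance(self):
        t = table([[-1], [1], [3], [5]], ["case", "case", "control", "control"])
        model = lda_fit(t)
        assert np.allclose(model.means.ravel(), [0.0, 4.0])
        assert model.covariance[0, 0] == pytest.approx(2.0)
        assert np.allclose(model.priors, [0.5, 0.5])
        assert model.ridge == 0.0

    def test_duplicated_column_triggers_ridge(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0], [3.0, 3.0]])
        model = lda_fit(table(x, ["case", "case", "control", "control"]))
        assert model.ridge > 0

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            lda_fit(table([[1.0], [2.0], [3.0]], ["case", "control", "control"]))


def one_d_model():
    # mu = (0, 2), sigma^2 = 1, equal priors
    from commpat.classify import LdaModel
    return LdaModel(("case", "control"), np.array([[0.0], [2.0]]),
                    np.array([[1.0]]), np.array([0.5, 0.5]))


class TestLdaPredict:
    def test_midpoint_is_even_posterior(self):
        _, post = lda_predict(one_d_model(), [1.0])
        assert np.allclose(post, [0.5, 0.5])

    def test_closed_form_posterior_at_zero(self):
        _, post = lda_predict(one_d_model(), [0.0])
        expected = np.exp(2) / (1 + np.exp(2))  # ~0.880797
        assert post[0] == pytest.approx(expected, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        model = one_d_model()
        _, post = lda_predict(model, rng.normal(size=(20, 1)))
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            lda_predict(one_d_model(), [[1.0, 2.0]])

    def test_decision_flips_at_mahalanobis_midplane(self, rng):
        # 2-D analytic check: equal priors, shared Sigma -> boundary is the
        # hyperplane of equal Mahalanobis distance to the two means
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu0, mu1 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        chol = np.linalg.cholesky(cov)
        x0 = mu0 + rng.standard_normal((50, 2)) @ chol.T
        x1 = mu1 + rng.standard_normal((50, 2)) @ chol.T
        t = FeatureTable(np.vstack([x0, x1]),
                         np.array(["case"] * 50 + ["control"] * 50), ["a", "b"])
        model = lda_fit(t)
        cov_inv = np.linalg.inv(model.covariance)
        for point in rng.normal(1.0, 2.0, size=(30, 2)):
            d0 = (point - model.means[0]) @ cov_inv @ (point - model.means[0])
            d1 = (point - model.means[1]) @ cov_inv @ (point - model.means[1])
            label, _ = lda_predict(model, point)
            margin = d0 - d1 - 2 * np.log(model.priors[0] / model.priors[1])
            if abs(margin) > 1e-9:
                assert label == (model.classes[0] if margin < 0 else model.classes[1])


def test_lda_predictions_match_reference_implementation(rng):
    """Decision labels agree with an independent LDA implementation."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    x = np.vstack([rng.normal(0, 1, size=(25, 3)), rng.normal(0.8, 1, size=(25, 3))])
    y = np.array(["case"] * 25 + ["control"] * 25)
    model = lda_fit(FeatureTable(x, y, ["a", "b", "c"]))
    xtest = rng.normal(0.4, 1.2, size=(40, 3))
    mine, _ = lda_predict(model, xtest)
    ref = LinearDiscriminantAnalysis().fit(x, y).predict(xtest)
    assert np.array_equal(mine, ref)


class TestKnn:
    train_x = np.array([[0.0], [0.1], [1.0], [1.1]])
    train_y = np.array(["B", "A", "A", "B"])

    def test_k1_nearest_label(self):
        assert knn_predict(self.train_x, self.train_y, [0.01], k=1) == "B"

    def test_k3_majority(self):
        assert knn_predict(self.train_x, self.train_y, [0.5], k=3) == "A"

    def test_k2_vote_tie_goes_to_nearest(self):
        assert knn_predict(self.train_x, self.train_y, [0.02], k=2) == "B"

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_predict(self.train_x, self.train_y, [0.0], k=9)


class TestPerformance:
    def test_confusion_example(self):
        y_true = ["case"] * 10 + ["control"] * 10
        y_pred = (["case"] * 8 + ["control"] * 2) + (["case"] * 2 + ["control"] * 8)
        assert performance(y_true, y_pred) == (80.0, 80.0, 80.0)

    def test_all_correct(self):
        y = ["case", "control", "case"]
        assert performance(y, y) == (100.0, 100.0, 100.0)

    def test_no_predicted_positives(self):
        acc, prec, rec = performance(["case", "control"], ["control", "control"])
        assert prec == 0.0 and rec == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            performance(["case"], ["case", "control"])


def separable_table(rng, n=20):
    x0 = rng.normal(0.0, 0.3, size=(n, 3))
    x1 = rng.normal(4.0, 0.3, size=(n, 3))
    return FeatureTable(np.vstack([x0, x1]),
                        np.array(["case"] * n + ["control"] * n),
                        ["f0", "f1", "f2"])


class TestCrossValidate:
    def test_separable_classes_perfect_loo(self, rng):
        rep = cross_validate(separable_table(rng), "lda", "loo", seed=0)
        assert rep.accuracy == 100.0
        rep_knn = cross_validate(separable_table(rng), "knn", "loo", seed=0)
        assert rep_knn.accuracy == 100.0

    def test_null_labels_near_chance(self, rng):
        accs = []
        for i in range(10):
            x = rng.normal(size=(40, 5))
            y = np.array(["case"] * 20 + ["control"] * 20)
            rep = cross_validate(FeatureTable(x, y, [f"f{j}" for j in range(5)]),
                                 "lda", "loo", seed=i)
            accs.append(rep.accuracy)
        assert 30 <= np.mean(accs) <= 70

    def test_same_seed_identical_reports(self, rng):
        t = separable_table(rng)
        a = cross_validate(t, "knn", "kfold", seed=7, n_folds=10)
        b = cross_validate(t, "knn", "kfold", seed=7, n_folds=10)
        assert a.to_dict() == b.to_dict()

    def test_stratified_folds_balanced(self):
        y = np.array(["case"] * 20 + ["control"] * 20)
        folds = stratified_folds(y, 10, seed=0)
        assert len(folds) == 10
        for f in folds:
            counts = [np.sum(y[f] == c) for c in ("case", "control")]
            assert abs(counts[0] - counts[1]) <= 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(40))

    def test_infeasible_kfold_rejected(self, rng):
        t = separable_table(rng, n=5)
        with pytest.raises(ValueError):
            cross_validate(t, "lda", "kfold", seed=0, n_folds=10)

    def test_no_leakage_from_test_fold(self, rng):
        """A held-out subject's own label never influences its prediction."""
        t = separable_table(rng, n=10)
        rep1 = cross_validate(t, "lda", "loo", seed=0)
        y2 = t.y.copy()
        y2[0] = "control" if y2[0] == "case" else "case"  # corrupt test label only
        rep2 = cross_validate(FeatureTable(t.x.copy(), y2, t.feature_names),
                              "lda", "loo", seed=0)

        def fold0_predicted_case(rep, truth):
            c = rep.fold_confusions[0]
            return (c["tp"] == 1) if truth == "case" else (c["fp"] == 1)

        assert fold0_predicted_case(rep1, t.y[0]) == fold0_predicted_case(rep2, y2[0])

    def test_reported_rates_match_confusions(self, rng):
        rep = cross_validate(separable_table(rng), "lda", "loo", seed=0)
        tp = sum(c["tp"] for c in rep.fold_confusions)
        fp = sum(c["fp"] for c in rep.fold_confusions)
        fn = sum(c["fn"] for c in rep.fold_confusions)
        tn = sum(c["tn"] for c in rep.fold_confusions)
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + fn + tn))
        assert rep.precision == pytest.approx(100 * tp / (tp + fp))
        assert rep.recall == pytest.approx(100 * tp / (tp + fn))


class TestRfe:
    def test_single_feature_scores_one(self, rng):
        t = FeatureTable(rng.normal(size=(20, 1)),
                         np.array(["case"] * 10 + ["control"] * 10), ["only"])
        assert rfe_rank(t).scores == {"only": 1.0}

    def test_informative_feature_ranked_top(self, rng):
        hits = 0
        for i in range(5):
            n = 20
            y = np.array(["case"] * n + ["control"] * n)
            signal = np.concatenate([rng.normal(0, 0.4, n), rng.normal(2, 0.4, n)])
            x = np.column_stack([signal] + [rng.normal(size=2 * n) for _ in range(4)])
            t = FeatureTable(x, y, ["signal", "n1", "n2", "n3", "n4"])
            ranking = rfe_rank(t, "lda", seed=i)
            top = max(ranking.scores, key=ranking.scores.get)
            hits += top == "signal"
        assert hits >= 4

    def test_scores_in_unit_interval_and_equivariant(self, rng):
        n = 12
        y = np.array(["case"] * n + ["control"] * n)
        x = rng.normal(size=(2 * n, 4))
        t = FeatureTable(x, y, ["a", "b", "c", "d"])
        r1 = rfe_rank(t, seed=3)
        assert all(0.0 <= v <= 1.0 for v in r1.scores.values())
        perm = [2, 0, 3, 1]
        t2 = FeatureTable(x[:, perm], y, [["a", "b", "c", "d"][i] for i in perm])
        r2 = rfe_rank(t2, seed=3)
        assert r1.scores == r2.scores
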