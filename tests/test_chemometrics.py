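"""PCA, PLS-DA, Mahalanobis binomialization, ROC/AUC and confusion metrics."""

import numpy as np
import pytest

import neuroraman.chemometrics as chem
from neuroraman.chemometrics import (
    ConfusionCounts,
    MahalanobisClassifier,
    confusion_metrics,
    fit_mahalanobis,
    fit_pca,
    fit_plsda,
    kfold_pca_classify,
    mahalanobis_binomialize,
    plsda_evaluate,
    rmse,
    roc_auc,
)
from neuroraman.exceptions import InvalidParameterError, StratificationError


def _blobs(rng, n=30, sep=6.0, dim=8):
    """Two well-separated Gaussian classes."""
    a = rng.standard_normal((n, dim))
    b = rng.standard_normal((n, dim))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.array(["neg"] * n + ["pos"] * n)
    return X, y


class TestPCA:
    def test_identical_rows_zero_variance(self):
        X = np.tile(np.arange(10.0), (5, 1))
        model = fit_pca(X, n_components=2)
        np.testing.assert_allclose(model.explained_variance_ratio, 0.0)
        np.testing.assert_allclose(model.scores, 0.0, atol=1e-12)

    def test_rank_one_data(self, rng):
        t = rng.standard_normal(12)
        X = np.column_stack([2 * t, -t])
        model = fit_pca(X, n_components=2)
        np.testing.assert_allclose(model.explained_variance_ratio, [1.0, 0.0],
                                   atol=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 50))
        model = fit_pca(X, n_components=5)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio,
            evals[:5] / evals.sum(), atol=1e-8)
        for i in range(5):
            cos = abs(model.loadings[i] @ evecs[:, i])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((10, 6))
        model = fit_pca(X, n_components=6)
        np.testing.assert_allclose(model.reconstruct(model.scores), X, atol=1e-8)

    def test_loadings_orthonormal_and_evr_sorted(self, rng):
        X = rng.standard_normal((15, 30))
        model = fit_pca(X, n_components=5)
        G = model.loadings @ model.loadings.T
        np.testing.assert_allclose(G, np.eye(5), atol=1e-8)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((12, 9))
        m1, m2 = fit_pca(X, 3), fit_pca(X.copy(), 3)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        for i in range(3):
            assert m1.loadings[i, np.argmax(np.abs(m1.loadings[i]))] > 0

    def test_too_many_components_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            fit_pca(rng.standard_normal((4, 10)), n_components=4)


class TestKFoldClassify:
    def test_separated_classes_perfect_accuracy(self, rng):
        X, y = _blobs(rng)
        res = kfold_pca_classify(X, y, k=5, n_components=5, rng=0)
        assert res["mean_accuracy"] == 1.0

    def test_pure_noise_is_chance_level(self):
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((60, 20))
            y = np.array(["a", "b"] * 30)
            accs.append(kfold_pca_classify(X, y, k=5, n_components=5,
                                           rng=seed)["mean_accuracy"])
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_leave_one_out_on_four_points(self):
        X = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        y = np.array(["a", "a", "b", "b"])
        res = kfold_pca_classify(X, y, k=4, n_components=1)
        assert res["mean_accuracy"] == 1.0

    def test_class_smaller_than_k_raises(self, rng):
        X = rng.standard_normal((7, 4))
        y = np.array(["a"] * 5 + ["b"] * 2)
        with pytest.raises(StratificationError):
            kfold_pca_classify(X, y, k=5)

    def test_fold_honesty_pca_never_sees_test_rows(self, rng, monkeypatch):
        # leakage (PCA on all rows) would be a different code path; assert
        # every PCA fit inside CV sees strictly fewer rows than the dataset
        X, y = _blobs(rng, n=10)
        seen = []
        real = chem.fit_pca

        def spy(data, n_components=5):
            seen.append(np.asarray(data).shape[0])
            return real(data, n_components)

        monkeypatch.setattr(chem, "fit_pca", spy)
        kfold_pca_classify(X, y, k=5, n_components=3, rng=0)
        assert len(seen) == 5
        assert all(n == 16 for n in seen)       # 4/5 of 20 rows, never 20


class TestPLSDA:
    def test_single_informative_coordinate_dominates_first_weight(self, rng):
        X = rng.standard_normal((40, 10)) * 0.01
        y = np.array(["a", "b"] * 20)
        X[y == "b", 3] += 5.0
        model = fit_plsda(X, y, n_components=3)
        w1 = model.weights[:, 0]
        assert abs(w1[3]) / np.linalg.norm(w1) > 0.99

    def test_first_weight_is_centered_covariance_direction(self, rng):
        # closed-form first NIPALS direction: w1 ∝ Xcᵀ yc
        X, y = _blobs(rng, n=15, sep=3.0)
        model = fit_plsda(X, y, n_components=2)
        yc = (y == "pos").astype(float)
        yc -= yc.mean()
        expected = (X - X.mean(axis=0)).T @ yc
        cos = abs(model.weights[:, 0] @ expected) / (
            np.linalg.norm(model.weights[:, 0]) * np.linalg.norm(expected))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_scores_mutually_orthogonal(self, rng):
        X, y = _blobs(rng, n=20, sep=2.0, dim=15)
        model = fit_plsda(X, y, n_components=5)
        T = model.scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.outer(np.diag(G), np.diag(G)))
        assert np.max(np.abs(off) / norms) < 1e-6

    def test_invariant_to_global_additive_offset(self, rng):
        X, y = _blobs(rng, n=12)
        m1 = fit_plsda(X, y, n_components=3)
        m2 = fit_plsda(X + 17.5, y, n_components=3)
        np.testing.assert_allclose(m1.scores, m2.scores, atol=1e-8)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(InvalidParameterError):
            fit_plsda(X, np.array(["a"] * 10))


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self, rng):
        centroids = np.array([[0.0, 0, 0], [3.0, 1, -2]])
        clf = MahalanobisClassifier(("a", "b"), centroids, np.eye(3), 0.0)
        pts = rng.standard_normal((50, 3)) * 3
        d_euc = np.array([[np.linalg.norm(p - c) for c in centroids]
                          for p in pts])
        expected = np.where(d_euc[:, 0] <= d_euc[:, 1], "a", "b")
        np.testing.assert_array_equal(clf.predict(pts), expected)
        np.testing.assert_allclose(clf.distances(pts), d_euc, atol=1e-12)

    def test_hand_computed_2d_case(self):
        # centroids (0,0), (4,0); covariance diag(4,1); test point (1,0)
        clf = MahalanobisClassifier(("c0", "c1"),
                                    np.array([[0.0, 0.0], [4.0, 0.0]]),
                                    np.diag([1 / 4.0, 1.0]), 0.0)
        d = clf.distances([[1.0, 0.0]])[0]
        assert d[0] == pytest.approx(0.5)
        assert d[1] == pytest.approx(1.5)
        assert clf.predict([[1.0, 0.0]])[0] == "c0"

    def test_point_at_positive_centroid(self, rng):
        X = np.vstack([rng.standard_normal((20, 3)),
                       rng.standard_normal((20, 3)) + 4.0])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = fit_mahalanobis(X, y)
        pred = clf.predict(clf.class_centroids[1:])
        assert pred[0] == "b"
        assert clf.decision_scores(clf.class_centroids[1:])[0] > 0

    def test_singular_covariance_with_zero_ridge_raises(self):
        X = np.array([[0.0, 0], [0, 0], [1, 0], [1, 0.0]])  # dim 2 collapsed
        y = np.array(["a", "a", "b", "b"])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_mahalanobis(X, y, ridge_lambda=0.0)

    def test_affine_invariance_of_decisions(self, rng):
        Xtr = np.vstack([rng.standard_normal((25, 4)),
                         rng.standard_normal((25, 4)) + 2.0])
        ytr = np.array(["a"] * 25 + ["b"] * 25)
        Xte = rng.standard_normal((30, 4)) + 1.0
        pred1, _, _ = mahalanobis_binomialize(Xtr, ytr, Xte, ridge_lambda=0.0)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        b = rng.standard_normal(4)
        pred2, _, _ = mahalanobis_binomialize(Xtr @ A + b, ytr, Xte @ A + b,
                                              ridge_lambda=0.0)
        np.testing.assert_array_equal(pred1, pred2)


class TestConfusionMetrics:
    @pytest.mark.parametrize("counts, expect", [
        (ConfusionCounts(tp=30, fp=0, tn=0, fn=0), {"sensitivity": 1.0}),
        (ConfusionCounts(tp=0, fp=1, tn=49, fn=0), {"specificity": 0.98}),
        (ConfusionCounts(tp=5, fp=5, tn=5, fn=5), {"accuracy": 0.5}),
    ])
    def test_printed_formulas(self, counts, expect):
        metrics = confusion_metrics(counts)
        for key, val in expect.items():
            assert metrics[key] == pytest.approx(val)

    def test_enumerated_tables_match_rational_formulas(self):
        from fractions import Fraction

        for tp in range(3):
            for fp in range(3):
                for tn in range(3):
                    for fn in range(3):
                        if tp + fp + tn + fn == 0:
                            continue
                        m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
                        if tp + fn:
                            assert m["sensitivity"] == float(Fraction(tp, tp + fn))
                        else:
                            assert "sensitivity" in m["undefined"]
                        if tn + fp:
                            assert m["specificity"] == float(Fraction(tn, tn + fp))
                        assert m["accuracy"] == float(
                            Fraction(tp + tn, tp + fp + tn + fn))

    def test_zero_denominator_flagged_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=3, tn=4, fn=0))
        assert np.isnan(m["sensitivity"])
        assert m["undefined"] == ["sensitivity"]


class TestROC:
    def test_perfect_separation(self):
        curve = roc_auc([0.1, 0.2, 0.8, 0.9], ["n", "n", "p", "p"])
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_auc([0.5] * 10, ["n", "p"] * 5)
        assert curve.auc == pytest.approx(0.5)

    def test_matches_mann_whitney_oracle(self, rng):
        scores = np.round(rng.standard_normal(40), 1)  # rounding makes ties
        labels = np.where(rng.random(40) < 0.5, "p", "n")
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        curve = roc_auc(scores, labels)
        pos = scores[labels == "p"]
        neg = scores[labels == "n"]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert curve.auc == pytest.approx(wins / (len(pos) * len(neg)),
                                          abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.standard_normal(30)
        labels = np.array(["n", "p"] * 15)
        curve = roc_auc(scores, labels)
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(30)
        labels = np.array(["n", "p"] * 15)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.tanh(scores) * 3 + 1, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(InvalidParameterError):
            roc_auc([0.1, 0.2], ["p", "p"])


class TestRmse:
    def test_exact_match_zero(self):
        assert rmse([0, 1, 0], [0, 1, 0]) == 0.0

    def test_constant_half_on_balanced_truth(self):
        assert rmse([0.5] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_hand_vector(self):
        assert rmse([0.1, 0.9, 0.2], [0, 1, 0]) == pytest.approx(np.sqrt(0.02))

    def test_empty_raises(self):
        with pytest.raises(InvalidParameterError):
            rmse([], [])


class TestPlsdaEvaluate:
    def test_duplicated_separable_rows_are_perfect(self, rng):
        X, y = _blobs(rng, n=10)
        Xd, yd = np.vstack([X] * 3, dtype=float), np.concatenate([y] * 3)
        ev = plsda_evaluate(Xd, yd, rng=0)
        assert ev.accuracy == 1.0
        assert ev.auc == 1.0

    def test_report_fields_and_summary(self, rng):
        X, y = _blobs(rng)
        ev = plsda_evaluate(X, y, rng=1)
        d = ev.as_dict()
        assert set(d) >= {"auc", "rmse", "sensitivity", "specificity",
                          "accuracy"}
        text = ev.summary()
        assert "AUC" in text and "sensitivity" in text
        assert ev.counts.total == ev.n_test

    def test_null_labels_near_chance(self):
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.standard_normal((60, 12))
            y = np.array(["a", "b"] * 30)
            aucs.append(plsda_evaluate(X, y, rng=seed).auc)
        assert 0.2 <= np.median(aucs) <= 0.8
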