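"""Chemometric machinery: PCA, PLS-DA, Mahalanobis binomialization, ROC.

The supervised decision chain mirrors the published analysis protocol:

1. spectra (rows of a preprocessed :class:`~neuroraman.spectra.SpectrumSet`)
   are reduced to five latent scores, either unsupervised (PCA) or
   supervised (PLS-DA regression onto the {0, 1} class indicator);
2. the five PLS scores per spectrum are *binomialized*: class centroids are
   computed from the training scores, a pooled within-class covariance
   defines a Mahalanobis metric, and each test spectrum is assigned to the
   class with the smaller Mahalanobis distance;
3. performance is summarized by the confusion-matrix metrics

   * sensitivity = TP / (TP + FN)
   * specificity = TN / (TN + FP)
   * accuracy    = (TP + TN) / (TP + TN + FP + FN)

   together with the ROC curve and its AUC over the continuous decision
   score d(class₀) − d(class₁), and the RMSE of the continuous PLS-DA
   prediction against the indicator.

The pooled covariance carries a small ridge (default 1e-6·trace/dim):
with ~16-30 spectra per class and 5 dimensions, a per-class covariance is
unstable and an exactly singular pooled one must not crash the metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from neuroraman.exceptions import (
    InvalidParameterError,
    StratificationError,
)
from neuroraman.spectra import SpectrumSet

__all__ = [
    "PCAModel",
    "PLSDAModel",
    "MahalanobisClassifier",
    "ConfusionCounts",
    "ROCCurve",
    "PLSDAEvaluation",
    "fit_pca",
    "kfold_pca_classify",
    "fit_plsda",
    "mahalanobis_binomialize",
    "confusion_metrics",
    "roc_auc",
    "rmse",
    "plsda_evaluate",
]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.matrix
    return np.atleast_2d(np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Principal components of a spectrum matrix.

    ``loadings`` rows are orthonormal spectral directions with a fixed sign
    convention (the largest-magnitude element of each loading is positive),
    so refitting the same data reproduces the same model bit-for-bit.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray                 # (n_components, n_points)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                   # (n_rows, n_components)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, data) -> np.ndarray:
        X = _as_matrix(data)
        return (X - self.mean_spectrum) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings + self.mean_spectrum


def fit_pca(data, n_components: int = 5) -> PCAModel:
    """Column-mean-centered SVD principal component analysis.

    The explained-variance ratio of component i is σᵢ²/Σⱼσⱼ² over *all*
    singular values, so the reported ratios match the eigen-spectrum of the
    sample covariance.
    """
    X = _as_matrix(data)
    n, p = X.shape
    if n < 2:
        raise InvalidParameterError("PCA needs at least 2 rows")
    if not 1 <= n_components <= min(n - 1, p):
        raise InvalidParameterError(
            f"n_components must be in [1, min(n-1, n_points)] = "
            f"[1, {min(n - 1, p)}], got {n_components}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    evr = (s**2 / total) if total > 0 else np.zeros_like(s)
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    # deterministic sign: largest-|.| element of each loading made positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAModel(mean, loadings, evr[:n_components], scores)


def kfold_pca_classify(data, labels, k: int = 5, n_components: int = 5,
                       rng=None) -> dict:
    """Fold-honest cross-validated PCA + linear SVM classification.

    Per fold the PCA is fitted on the training rows only and both partitions
    are projected through it; a maximum-margin linear classifier is trained
    on the training scores and scored on the held-out scores.  Scores are
    standardized per fold (statistics from the training partition only):
    unit-norm spectra give PCA scores of order 1e-2, which the hinge
    regularization would otherwise swamp.  ``k == n`` requests
    leave-one-out; otherwise folds are stratified.

    Returns ``{"mean_accuracy", "fold_accuracies"}``.
    """
    X = _as_matrix(data)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    if k == n:
        splitter = LeaveOneOut()
        splits = splitter.split(X)
    else:
        if counts.min() < k:
            raise StratificationError(
                f"every class needs >= k={k} members for stratified folds")
        seed = rng if isinstance(rng, (int, np.integer)) else None
        if isinstance(rng, np.random.Generator):
            seed = int(rng.integers(2**31 - 1))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)

    accuracies = []
    for train_idx, test_idx in splits:
        y_train = y[train_idx]
        if k != n and len(np.unique(y_train)) < len(classes):
            raise StratificationError("a class is absent from a training fold")
        nc = min(n_components, len(train_idx) - 1, X.shape[1])
        pca = fit_pca(X[train_idx], n_components=nc)
        scaler = StandardScaler().fit(pca.transform(X[train_idx]))
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(scaler.transform(pca.transform(X[train_idx])), y_train)
        pred = clf.predict(scaler.transform(pca.transform(X[test_idx])))
        accuracies.append(float(np.mean(pred == y[test_idx])))
    return {"mean_accuracy": float(np.mean(accuracies)),
            "fold_accuracies": accuracies}


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PLSDAModel:
    """Fitted two-class PLS-DA regression onto the {0, 1} class indicator.

    Latent components come from the iterative covariance-maximizing
    (NIPALS) deflation, so successive score vectors are mutually
    orthogonal.  ``classes[0]`` is coded 0 (the negative class),
    ``classes[1]`` is coded 1 (the positive class); ``coefficients`` map
    centered spectra to the continuous indicator prediction.
    """

    classes: tuple
    x_mean: np.ndarray
    weights: np.ndarray       # (n_points, n_components) X-weights
    x_loadings: np.ndarray    # (n_points, n_components)
    coefficients: np.ndarray  # (n_points,)
    intercept: float
    scores: np.ndarray        # (n_rows, n_components) training X-scores
    _pls: PLSRegression = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def transform(self, data) -> np.ndarray:
        """Project spectra onto the latent components (5 scores per row)."""
        return self._pls.transform(_as_matrix(data))

    def predict(self, data) -> np.ndarray:
        """Continuous indicator prediction in the vicinity of [0, 1]."""
        return self._pls.predict(_as_matrix(data)).ravel()

    def indicator(self, labels) -> np.ndarray:
        y = np.asarray(labels)
        return (y == self.classes[1]).astype(float)


def fit_plsda(data, labels, n_components: int = 5) -> PLSDAModel:
    """Fit a binary PLS-DA model (class indicator coded {0, 1}).

    The two class names are sorted; the second is the positive class.
    Multi-dose designs are handled one-vs-control by the caller.
    """
    X = _as_matrix(data)
    y_labels = np.asarray(labels)
    classes = np.unique(y_labels)
    if len(classes) != 2:
        raise InvalidParameterError(
            f"PLS-DA is binary; got {len(classes)} class(es)")
    if len(y_labels) < 6:
        raise InvalidParameterError("PLS-DA needs at least 6 samples")
    y = (y_labels == classes[1]).astype(float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    return PLSDAModel(
        classes=tuple(classes.tolist()),
        x_mean=pls._x_mean,
        weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        coefficients=pls.coef_.ravel(),
        intercept=float(np.ravel(pls.intercept_)[0]),
        scores=pls.x_scores_,
        _pls=pls,
    )


# ---------------------------------------------------------------------------
# Mahalanobis binomialization


@dataclass
class MahalanobisClassifier:
    """Nearest-centroid classifier under a pooled Mahalanobis metric."""

    class_labels: tuple
    class_centroids: np.ndarray            # (2, n_dims)
    pooled_covariance_inverse: np.ndarray  # (n_dims, n_dims), symmetric PD
    ridge_lambda: float

    def distances(self, scores) -> np.ndarray:
        """Mahalanobis distance of each row to each class centroid."""
        S = np.atleast_2d(np.asarray(scores, dtype=float))
        out = np.empty((S.shape[0], len(self.class_labels)))
        for c, mu in enumerate(self.class_centroids):
            d = S - mu
            out[:, c] = np.sqrt(np.einsum(
                "ij,jk,ik->i", d, self.pooled_covariance_inverse, d))
        return out

    def decision_scores(self, scores) -> np.ndarray:
        """d(class₀) − d(class₁): positive favors the positive class."""
        d = self.distances(scores)
        return d[:, 0] - d[:, 1]

    def predict(self, scores) -> np.ndarray:
        d = self.distances(scores)
        return np.asarray(self.class_labels)[np.argmin(d, axis=1)]


def fit_mahalanobis(scores_train, labels_train,
                    ridge_lambda: float | None = None) -> MahalanobisClassifier:
    """Build the binomializing classifier from training scores.

    The metric is the inverse of the pooled within-class sample covariance
    plus ``ridge_lambda·I``; the default ridge is ``1e-6·trace(Σ)/dim``.
    Passing ``ridge_lambda = 0`` on singular data raises with instructions
    to use a positive ridge.
    """
    S = np.atleast_2d(np.asarray(scores_train, dtype=float))
    y = np.asarray(labels_train)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidParameterError("need exactly 2 classes of training scores")
    dim = S.shape[1]
    centroids = np.vstack([S[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((dim, dim))
    n_total = 0
    for c, mu in zip(classes, centroids):
        d = S[y == c] - mu
        pooled += d.T @ d
        n_total += d.shape[0]
    pooled /= max(n_total - 2, 1)
    if ridge_lambda is None:
        ridge_lambda = 1e-6 * float(np.trace(pooled)) / dim
    pooled_r = pooled + ridge_lambda * np.eye(dim)
    try:
        # Cholesky both checks positive-definiteness and gives the inverse
        L = np.linalg.cholesky(pooled_r)
        inv = np.linalg.inv(L.T) @ np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; pass a positive ridge_lambda "
            "(or leave it at the default)") from exc
    inv = (inv + inv.T) / 2.0
    return MahalanobisClassifier(tuple(classes.tolist()), centroids, inv,
                                 float(ridge_lambda))


def mahalanobis_binomialize(scores_train, labels_train, scores_test,
                            ridge_lambda: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray, MahalanobisClassifier]:
    """Binomialize 5-D PLS scores by Mahalanobis nearest centroid.

    Returns ``(predicted_labels, decision_scores, classifier)`` where the
    decision score is d(class₀) − d(class₁) — continuous, for ROC curves.
    """
    clf = fit_mahalanobis(scores_train, labels_train, ridge_lambda)
    return clf.predict(scores_test), clf.decision_scores(scores_test), clf


# ---------------------------------------------------------------------------
# evaluation surface


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN bookkeeping of a binary decision."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predicted, truth, positive) -> "ConfusionCounts":
        pred = np.asarray(predicted)
        true = np.asarray(truth)
        pp, tp_ = pred == positive, true == positive
        return cls(tp=int(np.sum(pp & tp_)), fp=int(np.sum(pp & ~tp_)),
                   tn=int(np.sum(~pp & ~tp_)), fn=int(np.sum(~pp & tp_)))


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity and accuracy from the confusion counts.

    A zero denominator yields NaN for that metric plus an entry in the
    ``undefined`` list — never a silent 0.
    """
    out: dict = {"undefined": []}
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "accuracy": (counts.tp + counts.tn, counts.total),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = float("nan")
            out["undefined"].append(name)
        else:
            out[name] = num / den
    return out


@dataclass
class ROCCurve:
    """ROC curve over decision-score thresholds, plus its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls=":", color="gray")
        ax.set_xlabel("false-positive rate (1 − specificity)")
        ax.set_ylabel("true-positive rate")
        ax.legend()
        return ax


def roc_auc(decision_scores, true_labels, positive=None) -> ROCCurve:
    """ROC curve and AUC of a continuous score against binary truth.

    Ties are handled by the threshold sweep over unique scores, so the AUC
    equals the normalized Mann-Whitney rank-sum statistic (ties counted
    one-half).
    """
    scores = np.asarray(decision_scores, dtype=float)
    y = np.asarray(true_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise InvalidParameterError("ROC needs both classes present")
    positive = classes[1] if positive is None else positive
    fpr, tpr, thr = _sk_roc_curve(y, scores, pos_label=positive)
    return ROCCurve(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def rmse(predicted_indicator, true_indicator) -> float:
    """Root mean squared error of continuous predictions vs {0, 1} truth."""
    pred = np.asarray(predicted_indicator, dtype=float)
    true = np.asarray(true_indicator, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise InvalidParameterError("inputs must be non-empty and equal-length")
    return float(np.sqrt(np.mean((pred - true) ** 2)))


@dataclass
class PLSDAEvaluation:
    """Held-out evaluation report of the PLS-DA + Mahalanobis chain."""

    auc: float
    rmse: float
    sensitivity: float
    specificity: float
    accuracy: float
    counts: ConfusionCounts
    roc: ROCCurve
    model: PLSDAModel
    classifier: MahalanobisClassifier
    n_train: int
    n_test: int
    seed: int | None

    def as_dict(self) -> dict:
        return {"auc": self.auc, "rmse": self.rmse,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "accuracy": self.accuracy,
                "n_train": self.n_train, "n_test": self.n_test}

    def summary(self) -> str:
        c = self.counts
        return "\n".join([
            "PLS-DA + Mahalanobis binomial classification",
            f"positive class: {self.model.classes[1]!r}; "
            f"{self.n_train} train / {self.n_test} test spectra; "
            f"{self.model.n_components} latent components",
            f"confusion: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}",
            f"sensitivity = {self.sensitivity:.3f}   "
            f"specificity = {self.specificity:.3f}   "
            f"accuracy = {self.accuracy:.3f}",
            f"AUC = {self.auc:.3f}   RMSE = {self.rmse:.3f}",
        ])


def plsda_evaluate(data, labels, train_fraction: float = 0.8,
                   n_components: int = 5, ridge_lambda: float | None = None,
                   rng=None) -> PLSDAEvaluation:
    """The full supervised evaluation in one call.

    Random stratified 80/20 split → PLS-DA fit on the training rows →
    Mahalanobis binomialization of the test scores → confusion metrics,
    ROC/AUC on the decision score and RMSE of the continuous prediction.
    If a partition misses a class the split is redrawn once, then an error
    is raised.
    """
    X = _as_matrix(data)
    y = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seed = rng if isinstance(rng, (int, np.integer)) else None

    n = len(y)
    for _attempt in range(2):
        perm = gen.permutation(n)
        n_train = int(round(train_fraction * n))
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        ok = (len(np.unique(y[train_idx])) == 2 and
              len(np.unique(y[test_idx])) == 2)
        if ok:
            break
    else:
        raise StratificationError("a partition misses a class after resampling")

    model = fit_plsda(X[train_idx], y[train_idx], n_components=n_components)
    pred, decision, clf = mahalanobis_binomialize(
        model.scores, y[train_idx], model.transform(X[test_idx]),
        ridge_lambda=ridge_lambda)
    positive = model.classes[1]
    counts = ConfusionCounts.from_predictions(pred, y[test_idx], positive)
    metrics = confusion_metrics(counts)
    curve = roc_auc(decision, y[test_idx], positive=positive)
    err = rmse(model.predict(X[test_idx]), model.indicator(y[test_idx]))
    return PLSDAEvaluation(
        auc=curve.auc, rmse=err,
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        accuracy=metrics["accuracy"], counts=counts, roc=curve, model=model,
        classifier=clf, n_train=len(train_idx), n_test=len(test_idx),
        seed=None if seed is None else int(seed))
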