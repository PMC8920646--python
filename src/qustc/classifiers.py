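"""Classifier roster: Mahalanobis KNN, linear SVM and random forest.

Scores are oriented so that larger means malignant (positive class 1): the
malignant vote fraction for KNN, the signed margin for the SVM and the
malignant tree fraction for the forest.  Hard labels use each model's
natural threshold (majority vote / zero margin / 0.5).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["MahalanobisKNN", "make_classifier", "predict_scores", "CLASSIFIER_KINDS"]

CLASSIFIER_KINDS = ("knn", "svm_linear", "random_forest")


class MahalanobisKNN(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbor classifier under the Mahalanobis metric.

    The metric's inverse covariance is estimated from the training features
    at fit time, with a ridge added to the diagonal if the covariance is
    (near-)singular.

    Parameters
    ----------
    n_neighbors
        K, odd (default 5) so majority votes cannot tie.
    ridge
        Relative diagonal loading applied when the covariance is
        ill-conditioned.
    """

    def __init__(self, n_neighbors: int = 5, ridge: float = 1e-8):
        self.n_neighbors = n_neighbors
        self.ridge = ridge

    def fit(self, X, y):
        if self.n_neighbors < 1 or self.n_neighbors % 2 == 0:
            raise ValueError("n_neighbors must be odd and >= 1")
        X, y = validate_data(self, X, y)
        cov = np.atleast_2d(np.cov(X, rowvar=False))
        scale = np.trace(cov) / cov.shape[0]
        if scale == 0:
            raise ValueError("degenerate training features: zero covariance trace")
        for attempt in range(2):
            loaded = cov + (self.ridge if attempt == 0 else 1e-3) * scale * np.eye(
                cov.shape[0]
            )
            if np.linalg.cond(loaded) < 1e12:
                break
        else:
            raise ValueError("training covariance singular even after regularization")
        self._knn = KNeighborsClassifier(
            n_neighbors=self.n_neighbors,
            metric="mahalanobis",
            metric_params={"VI": np.linalg.inv(loaded)},
            algorithm="brute",
        ).fit(X, y)
        self.classes_ = self._knn.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "_knn")
        X = validate_data(self, X, reset=False)
        return self._knn.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self, "_knn")
        X = validate_data(self, X, reset=False)
        return self._knn.predict_proba(X)


def make_classifier(kind: str, seed: int = 0, **kwargs) -> BaseEstimator:
    """Instantiate one of the roster classifiers with study defaults."""
    if kind == "knn":
        return MahalanobisKNN(n_neighbors=kwargs.pop("n_neighbors", 5), **kwargs)
    if kind == "svm_linear":
        return make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=kwargs.pop("C", 1.0), **kwargs)
        )
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=kwargs.pop("n_estimators", 100),
            max_features="sqrt",
            random_state=seed,
            **kwargs,
        )
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


def predict_scores(model, X) -> np.ndarray:
    """Continuous scores oriented so larger implies the positive class (1)."""
    classes = list(
        model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    )
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, classes.index(1)]
    # decision_function is positive toward classes_[1]
    scores = model.decision_function(X)
    return scores if classes[1] == 1 else -scores
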