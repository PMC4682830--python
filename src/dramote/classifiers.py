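"""The six-classifier benchmark roster and a uniform scoring surface.

SVM (linear and RBF kernels, default cost), K-nearest neighbours with K=3,
linear discriminant analysis, Gaussian naive Bayes, and a seeded
500-tree random forest.  ``minority_score`` maps every member onto a
continuous score for the +1 class in [0, 1]: probability outputs pass
through, margin outputs go through a logistic squash.
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["ROSTER", "make_classifier", "minority_score"]

ROSTER = ("svm_linear", "svm_rbf", "knn", "lda", "nb", "rf")


def make_classifier(name: str, seed: int = 0, rf_trees: int = 500):
    """Instantiate a roster member with the benchmark's default settings."""
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "nb":
        return GaussianNB()
    if name == "rf":
        return RandomForestClassifier(n_estimators=rf_trees, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; roster: {ROSTER}")


def minority_score(clf, X: np.ndarray) -> np.ndarray:
    """Continuous score for the +1 class, in [0, 1].

    Fitted on a single class (degenerate resamples), returns the constant
    0/1 score of that class.
    """
    classes = np.asarray(clf.classes_)
    if classes.shape[0] == 1:
        return np.full(X.shape[0], 1.0 if classes[0] == 1 else 0.0)
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        return proba[:, int(np.flatnonzero(classes == 1)[0])]
    # margin classifiers: decision_function is positive towards classes_[1]
    d = np.asarray(clf.decision_function(X), dtype=float)
    if classes[1] != 1:
        d = -d
    return 1.0 / (1.0 + np.exp(-d))
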