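"""Reference machine-learning baselines, delegated to scikit-learn.

Random forest (tree count selected from {20, 40, 60, 80, 100} by internal
cross-validation, depth capped at 10) and a linear-kernel SVM (margin penalty
C from {0.2, 0.4, 0.6, 0.8, 1.0}). Both consume the same input representation
as the attention detector and plug into :func:`hfodet.evalrec.evaluate`
through the classifier-closure interface. SVM "probabilities" are the
logistic squash of the decision margin — monotone in the margin, which is all
ranking and a 0.5 threshold (= sign of the margin) need.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.svm import LinearSVC

from hfodet.attnmodel import ModelSpec, prepare_inputs

RF_TREE_GRID = (20, 40, 60, 80, 100)
RF_MAX_DEPTH = 10
SVM_C_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


def _features(segments, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    x = prepare_inputs(segments, spec, dtype="float64")
    y = np.array([s.y for s in segments])
    return x, y


def random_forest_classifier(spec: ModelSpec, cv: int = 3):
    """Closure ``(train_segments, test_segments, seed) -> probabilities``."""

    def fit_predict(train_segments, test_segments, seed):
        xtr, ytr = _features(train_segments, spec)
        xte, _ = _features(test_segments, spec)
        search = GridSearchCV(
            RandomForestClassifier(max_depth=RF_MAX_DEPTH, random_state=seed),
            {"n_estimators": list(RF_TREE_GRID)},
            cv=cv,
            n_jobs=1,
        )
        search.fit(xtr, ytr)
        return search.best_estimator_.predict_proba(xte)[:, 1]

    return fit_predict


def linear_svm_classifier(spec: ModelSpec, cv: int = 3):
    """Closure ``(train_segments, test_segments, seed) -> probabilities``."""

    def fit_predict(train_segments, test_segments, seed):
        xtr, ytr = _features(train_segments, spec)
        xte, _ = _features(test_segments, spec)
        mu, sd = xtr.mean(), xtr.std() or 1.0
        search = GridSearchCV(
            LinearSVC(random_state=seed),
            {"C": list(SVM_C_GRID)},
            cv=cv,
            n_jobs=1,
        )
        search.fit((xtr - mu) / sd, ytr)
        return expit(search.best_estimator_.decision_function((xte - mu) / sd))

    return fit_predict


BASELINE_FACTORIES = {
    "rf": random_forest_classifier,
    "svm": linear_svm_classifier,
}
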