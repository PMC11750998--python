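"""Random undersampling boosting (RUSBoost).

AdaBoost.M1 where, before each boosting round, the majority class is
randomly undersampled to the minority-class size; the weak learner is fit
on the balanced subsample (with the current boosting weights) but the
weight update runs on the full training set. This keeps the ensemble
sensitive to the minority class under class imbalance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["RUSBoostClassifier"]


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Binary RUSBoost ensemble of decision stumps.

    Parameters
    ----------
    n_estimators : boosting rounds.
    learning_rate : shrinkage on the per-round ensemble weights.
    estimator : weak learner prototype (default depth-1 decision tree).
    random_state : seed for the per-round undersampling.
    """

    def __init__(
        self,
        n_estimators: int = 50,
        learning_rate: float = 1.0,
        estimator=None,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoostClassifier is binary only")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        yi = (y == self.classes_[1]).astype(int)
        counts = np.bincount(yi, minlength=2)
        minority = int(np.argmin(counts))
        w = np.full(n, 1.0 / n)
        self.estimators_: list = []
        self.estimator_weights_: list[float] = []
        proto = self.estimator or DecisionTreeClassifier(max_depth=1)
        for _ in range(self.n_estimators):
            idx_min = np.nonzero(yi == minority)[0]
            idx_maj = np.nonzero(yi != minority)[0]
            take = rng.choice(idx_maj, size=len(idx_min), replace=False)
            idx = np.concatenate([idx_min, take])
            est = clone(proto)
            est.fit(X[idx], yi[idx], sample_weight=w[idx] * n)
            pred = est.predict(X)
            err = float(w[pred != yi].sum() / w.sum())
            if err <= 0:
                self.estimators_.append(est)
                self.estimator_weights_.append(1.0)
                break
            if err >= 0.5:
                # weak learner no better than chance on the weighted set
                if not self.estimators_:
                    self.estimators_.append(est)
                    self.estimator_weights_.append(1e-10)
                break
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / err)
            self.estimators_.append(est)
            self.estimator_weights_.append(alpha)
            w *= np.exp(alpha * (2 * (pred != yi) - 1))
            w /= w.sum()
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for est, a in zip(self.estimators_, self.estimator_weights_):
            score += a * (2 * est.predict(X) - 1)
        total = sum(self.estimator_weights_)
        return score / total if total > 0 else score

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        d = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-2.0 * d))
        return np.column_stack([1 - p1, p1])
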