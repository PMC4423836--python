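"""A small bank of classifiers over binary indicator features.

Each learner is written out from its defining computation rather than
wrapped from an external library: Bernoulli naive Bayes with Laplace
smoothing, logistic regression fit by batch gradient ascent, k-nearest
neighbours under Hamming distance, and a one-hidden-layer sigmoid network
trained by backpropagation.  The feature-selection protocol only needs
``fit`` + ``predict`` and is agnostic to which subset of the bank is
enabled; the bank is pluggable so further learners can be registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LEARNER_KINDS = ("naive_bayes", "logistic", "knn", "mlp")


class LearnerError(ValueError):
    pass


def _check_training_data(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise LearnerError("X and y shapes are inconsistent")
    if X.shape[0] < 2:
        raise LearnerError("need at least 2 training rows")
    if np.unique(y).size < 2:
        raise LearnerError("training labels contain a single class")
    return X, y


class NaiveBayes:
    """Bernoulli naive Bayes with add-one (Laplace) smoothing."""

    def fit(self, X, y):
        X, y = _check_training_data(X, y)
        self.classes_ = np.array([0, 1])
        n = len(y)
        self.log_prior_ = np.log((np.array([(y == 0).sum(), (y == 1).sum()]) + 1) / (n + 2))
        theta = np.empty((2, X.shape[1]))
        for c in (0, 1):
            rows = X[y == c]
            theta[c] = (rows.sum(axis=0) + 1) / (len(rows) + 2)
        self.log_theta_ = np.log(theta)
        self.log_one_minus_theta_ = np.log1p(-theta)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = (
            X @ self.log_theta_.T
            + (1 - X) @ self.log_one_minus_theta_.T
            + self.log_prior_
        )
        return (scores[:, 1] > scores[:, 0]).astype(int)


class Logistic:
    """Logistic regression by full-batch gradient ascent on the
    log-likelihood with a small L2 penalty for stability."""

    def __init__(self, n_iter: int = 150, lr: float = 2.0, l2: float = 1e-3):
        self.n_iter, self.lr, self.l2 = n_iter, lr, l2

    def fit(self, X, y):
        X, y = _check_training_data(X, y)
        n, d = X.shape
        Xb = np.hstack([np.ones((n, 1)), X])
        w = np.zeros(d + 1)
        for _ in range(self.n_iter):
            p = 1.0 / (1.0 + np.exp(-np.clip(Xb @ w, -30, 30)))
            grad = Xb.T @ (y - p) / n - self.l2 * w
            w += self.lr * grad
        self.coef_ = w
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xb = np.hstack([np.ones((len(X), 1)), X])
        return (Xb @ self.coef_ > 0).astype(int)


class KNN:
    """k-nearest neighbours under Hamming distance, majority vote.

    Odd ``k`` avoids vote ties; distance ties resolve by training-row
    order (argsort stability), which keeps predictions deterministic.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X, y = _check_training_data(X, y)
        self.X_, self.y_ = X, y
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        # Hamming distance between 0/1 rows via two inner products
        d = X @ (1 - self.X_.T) + (1 - X) @ self.X_.T
        k = min(self.k, len(self.y_))
        nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
        votes = self.y_[nearest].mean(axis=1)
        return (votes > 0.5).astype(int)


class MLP:
    """One hidden sigmoid layer trained by full-batch backpropagation on
    squared error; deterministic given ``seed``."""

    def __init__(self, hidden: int = 8, n_iter: int = 500, lr: float = 2.0, seed: int = 0):
        self.hidden, self.n_iter, self.lr, self.seed = hidden, n_iter, lr, seed

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))

    def fit(self, X, y):
        X, y = _check_training_data(X, y)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        self.W1 = rng.normal(0, 0.5, size=(d + 1, self.hidden))
        self.W2 = rng.normal(0, 0.5, size=(self.hidden + 1, 1))
        Xb = np.hstack([np.ones((n, 1)), X])
        t = y.reshape(-1, 1).astype(float)
        for _ in range(self.n_iter):
            H = self._sigmoid(Xb @ self.W1)
            Hb = np.hstack([np.ones((n, 1)), H])
            out = self._sigmoid(Hb @ self.W2)
            # backprop of squared error through both sigmoid layers
            delta_out = (out - t) * out * (1 - out)
            delta_hid = (delta_out @ self.W2[1:].T) * H * (1 - H)
            self.W2 -= self.lr * Hb.T @ delta_out / n
            self.W1 -= self.lr * Xb.T @ delta_hid / n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xb = np.hstack([np.ones((len(X), 1)), X])
        H = self._sigmoid(Xb @ self.W1)
        Hb = np.hstack([np.ones((len(X), 1)), H])
        return (self._sigmoid(Hb @ self.W2).ravel() > 0.5).astype(int)


_FACTORIES: dict[str, Callable] = {
    "naive_bayes": NaiveBayes,
    "logistic": Logistic,
    "knn": KNN,
    "mlp": MLP,
}


def register_learner(kind: str, factory: Callable) -> None:
    """Register an additional learner factory under ``kind``."""
    _FACTORIES[kind] = factory


def fit_learner(kind: str, X, y, **hyperparams):
    """Fit one learner of the given kind and return the fitted model."""
    if kind not in _FACTORIES:
        raise LearnerError(f"unknown learner kind {kind!r}; known: {sorted(_FACTORIES)}")
    return _FACTORIES[kind](**hyperparams).fit(X, y)


@dataclass
class LearnerBank:
    """The enabled subset of learners scoring candidate solutions.

    The default pair (naive Bayes + logistic) keeps the evolutionary search
    fast; ``knn`` and ``mlp`` can be enabled where their extra cost is
    acceptable.
    """

    enabled: tuple[str, ...] = ("naive_bayes", "logistic")
    hyperparams: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        if not self.enabled:
            raise LearnerError("learner bank must enable at least one learner")
        for kind in self.enabled:
            if kind not in _FACTORIES:
                raise LearnerError(f"unknown learner kind {kind!r}")

    def predictions(self, X_train, y_train, X_test) -> list[np.ndarray]:
        """Fit every enabled learner on the training block and return its
        predictions for the test block."""
        return [
            fit_learner(kind, X_train, y_train, **self.hyperparams.get(kind, {})).predict(X_test)
            for kind in self.enabled
        ]
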