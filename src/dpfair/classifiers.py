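"""Pluggable binary probabilistic classifiers.

The DP workflow is classifier-agnostic: any learner with
``fit(X, y, sample_weight=None, seed=0)`` and ``predict_proba1(X)``
(probability of the minority class C1) plugs in. Two learners ship:

``LogisticLearner``
    L2-regularized logistic regression, solved to tight tolerance. It is
    deterministic and convex with full per-sample-weight support, which
    makes it the reference learner for experiments and for the
    weight-vs-duplication equivalence (weight n and n copies give the
    same optimum exactly).

``MLPLearner``
    A small feed-forward network (one hidden layer by default), the kind
    of architecture typically used for tabular prognosis tasks.
    Architecture stays fixed across bias-correction methods so that only
    the training data differs between candidates. Integer per-sample
    weights are honored by exact row replication; non-integer weights
    are rejected (use ``LogisticLearner`` for continuous reweighting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

__all__ = ["LogisticLearner", "MLPLearner", "make_learner"]


def _check_binary(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")


@dataclass
class LogisticLearner:
    """Deterministic convex learner: standardized features + logistic fit."""

    c: float = 1.0
    max_iter: int = 5000
    tol: float = 1e-10

    def clone(self) -> "LogisticLearner":
        return LogisticLearner(c=self.c, max_iter=self.max_iter, tol=self.tol)

    def fit(self, X, y, sample_weight=None, seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _check_binary(y)
        self._scaler = StandardScaler().fit(X)
        self._clf = LogisticRegression(
            C=self.c, max_iter=self.max_iter, tol=self.tol, solver="lbfgs"
        )
        self._clf.fit(self._scaler.transform(X), y, sample_weight=sample_weight)
        return self

    def predict_proba1(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        idx = list(self._clf.classes_).index(1)
        return self._clf.predict_proba(self._scaler.transform(X))[:, idx]

    @property
    def coef_(self) -> np.ndarray:
        return self._clf.coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self._clf.intercept_[0])


@dataclass
class MLPLearner:
    """Small feed-forward network with a fixed architecture.

    ``seed`` passed to :meth:`fit` controls weight initialization and
    minibatch shuffling, so training is reproducible.
    """

    hidden: tuple[int, ...] = (16,)
    alpha: float = 1e-3
    max_iter: int = 300
    learning_rate_init: float = 1e-3

    def clone(self) -> "MLPLearner":
        return MLPLearner(
            hidden=self.hidden,
            alpha=self.alpha,
            max_iter=self.max_iter,
            learning_rate_init=self.learning_rate_init,
        )

    def fit(self, X, y, sample_weight=None, seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            if not np.allclose(w, np.round(w)):
                raise ValueError(
                    "MLPLearner supports integer sample weights only "
                    "(handled by row replication); use LogisticLearner "
                    "for continuous weights"
                )
            rep = np.repeat(np.arange(len(X)), np.round(w).astype(int))
            X, y = X[rep], y[rep]
        _check_binary(y)
        self._scaler = StandardScaler().fit(X)
        self._clf = MLPClassifier(
            hidden_layer_sizes=self.hidden,
            alpha=self.alpha,
            max_iter=self.max_iter,
            learning_rate_init=self.learning_rate_init,
            random_state=int(seed) % (2**31),
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(self._scaler.transform(X), y)
        return self

    def predict_proba1(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        idx = list(self._clf.classes_).index(1)
        return self._clf.predict_proba(self._scaler.transform(X))[:, idx]


def make_learner(name: str, **kwargs):
    """Learner factory used by the CLI (``logistic`` or ``mlp``)."""
    if name == "logistic":
        return LogisticLearner(**kwargs)
    if name == "mlp":
        return MLPLearner(**kwargs)
    raise ValueError(f"unknown learner {name!r} (expected 'logistic' or 'mlp')")
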