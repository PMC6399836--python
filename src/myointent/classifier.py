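"""Linear discriminant analysis with pooled within-class covariance.

The classifier models each class k as Gaussian with its own mean mu_k and a
single covariance Sigma shared across classes (pooled within-class
estimator, denominator N - K).  The resulting discriminant is linear:

    g_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + log(pi_k)

and the predicted class is argmax_k g_k(x).  A small ridge term lambda*I is
added to Sigma so that collinear feature columns (e.g. duplicated channels)
do not make the solve fail; all linear algebra goes through a Cholesky
factorization, never an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
from scipy import linalg as sla

from .features import FeatureMatrix


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is not positive definite even after regularization."""


@dataclass
class LDAModel:
    classes: list                # ordered class labels
    means: np.ndarray            # (K, D)
    pooled_cov: np.ndarray       # (D, D), includes the ridge term
    priors: np.ndarray           # (K,)
    regularization: float        # ridge lambda actually added
    _cho: tuple = None           # cached Cholesky factor

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.allclose(self.pooled_cov, self.pooled_cov.T, atol=1e-10):
            raise ValueError("pooled covariance must be symmetric")
        if np.any(self.priors < 0) or not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must be non-negative and sum to 1")
        if self._cho is None:
            try:
                self._cho = sla.cho_factor(self.pooled_cov, lower=True)
            except np.linalg.LinAlgError as e:
                raise SingularCovarianceError(
                    "pooled covariance singular after regularization") from e

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Sigma^-1 @ b via the cached Cholesky factorization."""
        return sla.cho_solve(self._cho, b)

    def to_json(self, path) -> None:
        payload = {
            "classes": [getattr(c, "code", str(c)) for c in self.classes],
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "priors": self.priors.tolist(),
            "regularization": self.regularization,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_lda(features: FeatureMatrix | np.ndarray, labels=None,
            priors: np.ndarray | None = None,
            ridge: float | None = None) -> LDAModel:
    """Fit class means and the pooled within-class covariance.

    Accepts either a :class:`FeatureMatrix` or a plain ``(X, labels)`` pair.
    ``ridge`` defaults to ``1e-6 x mean(diag(pooled_cov))``; priors default
    to uniform (the protocol balances trials across classes).  Classes are
    ordered by first appearance in ``labels``.
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.values, features.labels
    else:
        X, y = np.asarray(features, dtype=float), labels
    if y is None:
        raise ValueError("labels required")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = list(dict.fromkeys(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    K, (N, D) = len(classes), X.shape

    means = np.empty((K, D))
    scatter = np.zeros((D, D))
    y_arr = np.array([classes.index(lbl) for lbl in y])
    for k in range(K):
        Xk = X[y_arr == k]
        if Xk.shape[0] < 2:
            raise ValueError(f"class {classes[k]} has fewer than 2 windows")
        means[k] = Xk.mean(axis=0)
        Xc = Xk - means[k]
        scatter += Xc.T @ Xc
    pooled = scatter / (N - K)

    lam = ridge if ridge is not None else 1e-6 * float(np.mean(np.diag(pooled)))
    pooled_reg = pooled + lam * np.eye(D)
    pri = np.full(K, 1.0 / K) if priors is None else np.asarray(priors, float)
    return LDAModel(classes=classes, means=means, pooled_cov=pooled_reg,
                    priors=pri, regularization=lam)


def discriminant_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Score g_k(x) for each row of X and each class, shape (n, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    W = model.solve(model.means.T)                       # (D, K)
    bias = -0.5 * np.einsum("dk,kd->k", W, model.means) \
        + np.log(model.priors)
    return X @ W + bias


def predict(model: LDAModel, X: np.ndarray) -> list:
    """Argmax-score class per row.

    Ties resolve to the lowest class index in ``model.classes``; scores
    within a relative 1e-9 of the maximum count as tied, so an analytically
    exact tie (e.g. the midpoint of two symmetric classes) is not broken by
    rounding in the linear solve and confusion matrices stay reproducible.
    """
    scores = discriminant_scores(model, X)
    best = scores.max(axis=1, keepdims=True)
    tol = 1e-9 * (1.0 + np.abs(best))
    first_max = np.argmax(scores >= best - tol, axis=1)
    return [model.classes[i] for i in first_max]
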