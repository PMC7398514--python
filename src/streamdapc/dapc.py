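"""Discriminant analysis of principal components (DAPC), from scratch.

DAPC first reduces a samples x variables matrix by PCA, keeping the smallest
number of components whose cumulative explained variance reaches a stated
fraction (0.95 by default), then fits a linear discriminant on the retained
component scores: the discriminant axes maximise the ratio of between-group
to within-group scatter. Group membership of a new sample is assigned from
its position in discriminant space under a shared spherical-covariance
Gaussian model with training priors. Because every discriminant axis is a
linear combination of retained components, each original variable has a
composite coefficient per axis; its squared, per-axis-normalised value is
the variable's *contribution*, the quantity thresholded to pick indicator
taxa.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba``, fitted attributes with a trailing underscore) and
composes with scikit-learn pipelines and model selection.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)


class DAPC(ClassifierMixin, BaseEstimator):
    """PCA-reduced linear discriminant classifier.

    Parameters
    ----------
    variance_fraction : float in (0, 1], default 0.95
        Retain the smallest number of principal components whose cumulative
        explained-variance fraction reaches this value (clamped to
        ``[1, n_samples - 1]``). With 1.0 every positive-variance component
        is kept and the model is an ordinary linear discriminant analysis
        expressed in a rotated basis.
    n_pc : int, optional
        Retain exactly this many components instead (still clamped to the
        matrix rank and ``n_samples - 1``). Overrides ``variance_fraction``.
    scale : bool, default False
        Divide each centred variable by its standard deviation before the
        PCA. Off by default: abundance tables are analysed on a common
        depth, so centring alone preserves the abundance structure.
    ridge : float, default 1e-8
        Relative ridge added to the within-group scatter only when it is
        numerically singular (scatter trace x ``ridge`` / n_pc on the
        diagonal); logged when applied.

    Attributes
    ----------
    classes_ : ndarray
        Sorted group labels seen in training.
    center_, scale_ : ndarray of shape (n_features,)
        Training column means and (if ``scale``) standard deviations.
    pca_basis_ : ndarray of shape (n_features, n_pc_)
        Orthonormal principal-component loadings (sign fixed so each
        column's largest-magnitude element is positive).
    pca_eigenvalues_ : ndarray
        All PCA eigenvalues, descending.
    explained_variance_ratio_ : ndarray
        Per-component explained-variance fractions (all components).
    n_pc_ : int
        Number of retained components.
    da_coefficients_ : ndarray of shape (n_pc_, n_axes_)
        Map from component scores to discriminant scores, scaled so the
        pooled within-group covariance of each discriminant score is 1.
    group_centroids_ : ndarray of shape (n_classes, n_axes_)
        Group means in discriminant space.
    priors_ : ndarray of shape (n_classes,)
        Training class proportions.
    """

    def __init__(
        self,
        variance_fraction: float = 0.95,
        n_pc: int | None = None,
        scale: bool = False,
        ridge: float = 1e-8,
    ):
        self.variance_fraction = variance_fraction
        self.n_pc = n_pc
        self.scale = scale
        self.ridge = ridge

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "DAPC":
        X, feature_names = _as_matrix(X)
        y = np.asarray(y)
        if y.ndim != 1 or len(y) != X.shape[0]:
            raise ValueError("y must be one label per row of X")
        n, p = X.shape
        if n < 3:
            raise ValueError(f"need at least 3 samples, got {n}")
        if not (0.0 < self.variance_fraction <= 1.0):
            raise ValueError("variance_fraction must be in (0, 1]")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 distinct group labels")

        self.feature_names_in_ = feature_names
        self.n_features_in_ = p
        self.classes_ = classes
        self.center_ = X.mean(axis=0)
        Xc = X - self.center_
        if self.scale:
            sd = Xc.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            self.scale_ = sd
            Xc = Xc / sd
        else:
            self.scale_ = np.ones(p)

        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if rank == 0:
            raise ValueError("constant matrix: no variance to analyse")
        total_var = float(np.sum(s**2))
        ratio = s**2 / total_var
        if self.n_pc is not None:
            if self.n_pc < 1:
                raise ValueError("n_pc must be >= 1")
            k = self.n_pc
        else:
            k = int(np.searchsorted(np.cumsum(ratio), self.variance_fraction - 1e-12)) + 1
        k = max(1, min(k, rank, n - 1))

        V = Vt.T[:, :k].copy()
        # Deterministic sign: largest-magnitude loading positive per column.
        flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        V *= flip
        self.pca_basis_ = V
        self.pca_eigenvalues_ = s**2 / max(n - 1, 1)
        self.explained_variance_ratio_ = ratio
        self.n_pc_ = k

        Z = Xc @ V  # component scores, n x k
        G = len(classes)
        counts = np.bincount(y_idx, minlength=G).astype(float)
        self.priors_ = counts / n
        means = np.vstack([Z[y_idx == g].mean(axis=0) for g in range(G)])
        grand = Z.mean(axis=0)
        dev = means - grand
        Sb = (dev * counts[:, None]).T @ dev
        R = Z - means[y_idx]
        Sw = R.T @ R

        eigvals_w = np.linalg.eigvalsh(Sw)
        singular = eigvals_w[0] <= max(eigvals_w[-1], 0.0) * 1e-10
        if singular:
            eps = self.ridge * (np.trace(Sw) / k if np.trace(Sw) > 0 else 1.0)
            Sw = Sw + eps * np.eye(k)
            logger.debug(
                "within-group scatter singular (n=%d, groups=%d, n_pc=%d); "
                "ridge %.3g applied", n, G, k,
            )
        n_axes = min(G - 1, k)
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
        order = np.argsort(evals)[::-1][:n_axes]
        A = evecs[:, order]
        # Scale axes so the pooled within-group covariance of each
        # discriminant score is 1 (Euclidean distance = Mahalanobis).
        dof = max(n - G, 1)
        within_var = np.einsum("ij,jk,ki->i", A.T, Sw / dof, A)
        within_var[within_var <= 0] = 1.0
        A = A / np.sqrt(within_var)
        # Deterministic sign via the composite (variable-space) loadings.
        comp = V @ A
        flip = np.sign(comp[np.argmax(np.abs(comp), axis=0), np.arange(n_axes)])
        flip[flip == 0] = 1.0
        A *= flip
        self.da_coefficients_ = A
        self.da_eigenvalues_ = np.maximum(evals[order], 0.0)
        self.n_axes_ = n_axes
        self.group_centroids_ = means @ A
        return self

    # -- prediction --------------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Discriminant scores for ``X`` (n_samples x n_axes_)."""
        X = self._check_features(X)
        Xc = (X - self.center_) / self.scale_
        return Xc @ self.pca_basis_ @ self.da_coefficients_

    def predict_log_proba(self, X) -> np.ndarray:
        D = self.transform(X)
        d2 = ((D[:, None, :] - self.group_centroids_[None, :, :]) ** 2).sum(axis=2)
        log_post = np.log(self.priors_)[None, :] - 0.5 * d2
        return log_post - logsumexp(log_post, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior group probabilities; rows sum to 1."""
        return np.exp(self.predict_log_proba(X))

    def predict(self, X) -> np.ndarray:
        """Most probable group per sample; ties go to the lower-indexed
        (first) class in ``classes_``."""
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]

    def _check_features(self, X) -> np.ndarray:
        self._require_fitted()
        X, names = _as_matrix(X)
        if names is not None and self.feature_names_in_ is not None:
            train = list(self.feature_names_in_)
            if names != train:
                missing = sorted(set(train) - set(names))
                extra = sorted(set(names) - set(train))
                if missing or extra:
                    raise ValueError(
                        f"feature mismatch: missing {missing}, extra {extra}"
                    )
                # same set, different order: realign
                pos = {c: i for i, c in enumerate(names)}
                X = X[:, [pos[c] for c in train]]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        return X

    def _require_fitted(self) -> None:
        if not hasattr(self, "pca_basis_"):
            raise RuntimeError("this DAPC instance is not fitted yet")

    # -- interpretation ----------------------------------------------------

    def variable_contributions(self) -> np.ndarray | pd.DataFrame:
        """Per-variable, per-axis contributions.

        The composite coefficient of variable *j* on axis *a* is
        ``(pca_basis_ @ da_coefficients_)[j, a]``; the contribution is its
        square, normalised so each axis column sums to 1. Returns a
        DataFrame when the model was fitted on one.
        """
        self._require_fitted()
        comp = self.pca_basis_ @ self.da_coefficients_
        contrib = comp**2
        col_sums = contrib.sum(axis=0)
        nonzero = col_sums > 0
        contrib[:, nonzero] = contrib[:, nonzero] / col_sums[nonzero]
        if self.feature_names_in_ is not None:
            return pd.DataFrame(
                contrib,
                index=self.feature_names_in_,
                columns=[f"LD{a + 1}" for a in range(self.n_axes_)],
            )
        return contrib

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialise the fitted model to a single JSON document."""
        self._require_fitted()
        doc = {
            "params": self.get_params(),
            "classes": np.asarray(self.classes_).tolist(),
            "feature_names": self.feature_names_in_,
            "n_features": int(self.n_features_in_),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "pca_basis": _matrix_doc(self.pca_basis_),
            "pca_eigenvalues": self.pca_eigenvalues_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "n_pc": int(self.n_pc_),
            "da_coefficients": _matrix_doc(self.da_coefficients_),
            "da_eigenvalues": self.da_eigenvalues_.tolist(),
            "group_centroids": _matrix_doc(self.group_centroids_),
            "priors": self.priors_.tolist(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "DAPC":
        """Rebuild a fitted model from :meth:`to_json` output or a path."""
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text(encoding="utf-8")
        doc = json.loads(source)
        model = cls(**doc["params"])
        model.classes_ = np.asarray(doc["classes"])
        model.feature_names_in_ = doc["feature_names"]
        model.n_features_in_ = doc["n_features"]
        model.center_ = np.asarray(doc["center"])
        model.scale_ = np.asarray(doc["scale"])
        model.pca_basis_ = _matrix_from_doc(doc["pca_basis"])
        model.pca_eigenvalues_ = np.asarray(doc["pca_eigenvalues"])
        model.explained_variance_ratio_ = np.asarray(
            doc["explained_variance_ratio"]
        )
        model.n_pc_ = doc["n_pc"]
        model.da_coefficients_ = _matrix_from_doc(doc["da_coefficients"])
        model.da_eigenvalues_ = np.asarray(doc["da_eigenvalues"])
        model.group_centroids_ = _matrix_from_doc(doc["group_centroids"])
        model.priors_ = np.asarray(doc["priors"])
        model.n_axes_ = model.da_coefficients_.shape[1]
        return model


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_dapc(X, y, variance_fraction: float = 0.95, scale: bool = False) -> DAPC:
    """Fit a :class:`DAPC` model; thin functional wrapper."""
    return DAPC(variance_fraction=variance_fraction, scale=scale).fit(X, y)


def predict_dapc(model: DAPC, X) -> tuple[np.ndarray, np.ndarray]:
    """Labels and posterior probabilities for ``X`` under a fitted model."""
    return model.predict(X), model.predict_proba(X)


def variable_contributions(model: DAPC):
    """Per-variable, per-axis contributions of a fitted model."""
    return model.variable_contributions()


def loo_accuracy(
    X, y, variance_fraction: float = 0.95, scale: bool = False
) -> float:
    """Leave-one-out classification accuracy with a full refit per fold.

    Every fold refits the PCA and the discriminant on the remaining
    samples. A sample whose class has only one member is skipped with a
    warning (its class would vanish from its own training fold).
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    singleton = set(classes[counts < 2])
    if singleton:
        warnings.warn(
            f"leave-one-out: skipping samples of single-member classes "
            f"{sorted(singleton)}",
            stacklevel=2,
        )
    correct = 0
    evaluated = 0
    for i in range(len(y)):
        if y[i] in singleton:
            continue
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = DAPC(variance_fraction=variance_fraction, scale=scale)
        model.fit(X[mask], y[mask])
        correct += int(model.predict(X[i: i + 1])[0] == y[i])
        evaluated += 1
    if evaluated == 0:
        raise ValueError("no samples could be evaluated")
    return correct / evaluated


# ---------------------------------------------------------------------------
# Helpers


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    """Coerce to a validated float 2-D array, keeping DataFrame columns."""
    names = None
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X, names


def _matrix_doc(M: np.ndarray) -> dict:
    return {"shape": list(M.shape), "data": M.ravel(order="C").tolist()}


def _matrix_from_doc(doc: dict) -> np.ndarray:
    return np.asarray(doc["data"]).reshape(doc["shape"])
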