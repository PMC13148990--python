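"""Normalized K-dimensional PCA feature spaces for stimulus embeddings.

A feature space reduces a stimuli x D embedding matrix to K principal
components and rescales each component so that the projections of the fitting
stimuli have zero mean and unit standard deviation.  Held-out stimuli are
projected with the fitting set's mean and scale (no refit).  A deterministic
sign convention (largest-magnitude loading of each component positive) makes
refits reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FeatureSpace", "fit_space", "project", "gaussian_subset", "fix_signs"]


def fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude entry is positive."""
    comps = np.array(components, dtype=float, copy=True)
    lead = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(len(comps)), lead])
    signs[signs == 0] = 1.0
    return comps * signs[:, None]


class FeatureSpace(TransformerMixin, BaseEstimator):
    """PCA projection with per-dimension unit-s.d. normalization.

    Parameters
    ----------
    n_components : int
        Dimensionality K of the feature space (K >= 2).

    Attributes
    ----------
    mean_ : (D,) ndarray
        Mean of the fitting embeddings.
    components_ : (K, D) ndarray
        Orthonormal principal directions (rows), sign-fixed.
    scale_ : (K,) ndarray
        Standard deviation of the fitting-set scores per component.
    explained_variance_ratio_ : (K,) ndarray
        Fraction of total embedding variance per component, non-increasing.
    """

    def __init__(self, n_components: int = 60):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "FeatureSpace":
        X = np.asarray(X, dtype=float)
        K = self.n_components
        if K < 2:
            raise ValueError("n_components must be >= 2")
        n, D = X.shape
        if n <= K:
            raise ValueError(f"need more than K={K} stimuli, got {n}")
        if D < K:
            raise ValueError(f"embedding dimension D={D} is smaller than K={K}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s[0] * max(n, D) * np.finfo(float).eps if s.size else 0.0
        rank = int(np.sum(s > tol))
        if rank < K:
            raise ValueError(
                f"embedding matrix has rank {rank} < K={K}; "
                f"the largest attainable K is {rank}"
            )
        comps = fix_signs(Vt[:K])
        scores = Xc @ comps.T
        scale = scores.std(axis=0)
        self.components_ = comps
        self.scale_ = scale
        total_var = (s**2).sum()
        self.explained_variance_ratio_ = (s[:K] ** 2) / total_var
        self.n_features_in_ = D
        self.fit_stimulus_ids_ = None
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project embeddings into normalized feature units."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"embedding dimension {X.shape[-1]} does not match the "
                f"fitted space (D={self.n_features_in_})"
            )
        return ((X - self.mean_) @ self.components_.T) / self.scale_

    def inverse_transform(self, F: np.ndarray) -> np.ndarray:
        """Map normalized feature vectors back to embedding space."""
        check_is_fitted(self, "components_")
        return np.asarray(F, dtype=float) * self.scale_ @ self.components_ + self.mean_


def fit_space(embeddings: np.ndarray, K: int = 60, ids=None) -> FeatureSpace:
    """Fit a normalized K-dimensional PCA space on an embedding matrix."""
    space = FeatureSpace(n_components=K).fit(embeddings)
    if ids is not None:
        space.fit_stimulus_ids_ = np.asarray(ids)
    return space


def project(space: FeatureSpace, embeddings: np.ndarray) -> np.ndarray:
    """Project embeddings into a fitted feature space (no renormalization)."""
    return space.transform(embeddings)


def gaussian_subset(
    F: np.ndarray,
    category: np.ndarray,
    n_keep: int,
    ids: np.ndarray | None = None,
    reg: float = 1e-9,
) -> dict:
    """Most-typical stimuli per category under a maximum-likelihood Gaussian.

    For each category a multivariate Gaussian is fit (ML mean and covariance,
    ridge-regularized by ``reg`` times the mean diagonal variance), and the
    ``n_keep`` members with the highest density under their own category's fit
    are returned.  This removes distributional outliers so that axis-direction
    statistics cannot be driven by the shape of the stimulus distribution.
    """
    F = np.asarray(F, dtype=float)
    category = np.asarray(category)
    if ids is None:
        ids = np.arange(len(F))
    ids = np.asarray(ids)
    kept: dict = {}
    for cat in np.unique(category):
        m = category == cat
        if m.sum() < n_keep:
            raise ValueError(f"category {cat!r} has fewer than n_keep={n_keep} stimuli")
        Xc = F[m]
        mean = Xc.mean(axis=0)
        cov = np.cov(Xc, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
        cov += reg * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
        try:
            logpdf = stats.multivariate_normal(mean, cov).logpdf(Xc)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular covariance for category {cat!r} after regularization"
            ) from err
        order = np.argsort(-np.atleast_1d(logpdf), kind="stable")
        kept[cat] = ids[m][order[:n_keep]]
    return kept
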