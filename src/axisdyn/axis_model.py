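"""Closed-form preferred-axis estimation with train/test evaluation.

A cell's preferred axis is the weight vector ``c`` such that its response to a
stimulus with normalized features ``f`` is approximately ``<c, f>`` plus the
mean rate: ``c = (r - r̄) F (FᵀF)⁻¹`` on the training stimuli, evaluated as R²
on held-out stimuli.  The module also provides cross-category prediction
(face axis on object responses and vice versa), the split-half-normalized
face-object axis correlation, the single-axis artificial-unit control, and the
response-magnitude control subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PreferredAxis",
    "PreferredAxisModel",
    "fit_axis",
    "fit_axes_population",
    "cross_predict",
    "cosine",
    "normalized_fo_correlation",
    "artificial_unit_control",
    "effectiveness_subsets",
    "shuffle_control_r2",
    "train_test_split_ids",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; NaN if either vector has zero norm."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(u @ v / (nu * nv))


def cosine_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise cosine similarity between two (n, K) arrays; NaN on zero norm."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = np.linalg.norm(A, axis=-1)
    nb = np.linalg.norm(B, axis=-1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.einsum("...k,...k->...", A, B) / denom
    return np.where(denom == 0, np.nan, out)


@dataclass
class PreferredAxis:
    """Fitted encoding axis of one cell over one time window and category."""

    weights: np.ndarray  # (K,) Hz per feature-unit
    mean_rate: float  # training-set mean rate, Hz
    r2_train: float
    r2_test: float
    window_ms: tuple[float, float] | None = None
    category: str | None = None
    cell_id: int | str | None = None
    feature_mean: np.ndarray | None = None  # training-set feature mean

    def predict(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        if self.feature_mean is not None:
            F = F - self.feature_mean
        return F @ self.weights + self.mean_rate


class PreferredAxisModel(RegressorMixin, BaseEstimator):
    """Linear encoding model ``r ≈ <w, f> + const`` fit by least squares.

    Responses are centered by the training-set mean rate, and by default
    features are centered by their training-set mean as well, which is
    equivalent to ordinary least squares with a free intercept.  The
    closed-form weights ``w = (r - r̄) F (FᵀF)⁻¹`` coincide with this fit
    exactly when the features have zero mean over the regression set; for a
    category whose features have a nonzero mean under the global
    normalization (e.g. faces in a mixed-category space), the free intercept
    removes a mean-offset bias in the recovered direction.
    ``center_features=False`` reproduces the raw closed form (intercept
    pinned to r̄).  With ``ridge > 0`` the normal equations are
    Tikhonov-regularized.

    Attributes
    ----------
    weights_ : (K,) ndarray
    mean_rate_ : float, training-set mean rate
    feature_mean_ : (K,) ndarray, training-set feature mean (zeros if uncentered)
    """

    def __init__(self, ridge: float = 0.0, center_features: bool = True):
        self.ridge = ridge
        self.center_features = center_features

    def fit(self, F: np.ndarray, r: np.ndarray) -> "PreferredAxisModel":
        F = np.asarray(F, dtype=float)
        r = np.asarray(r, dtype=float)
        n, K = F.shape
        self.mean_rate_ = float(r.mean())
        self.feature_mean_ = F.mean(axis=0) if self.center_features else np.zeros(K)
        Fc = F - self.feature_mean_
        G = Fc.T @ Fc
        if self.ridge > 0:
            G = G + self.ridge * np.eye(K)
        else:
            rank = np.linalg.matrix_rank(G)
            if rank < K:
                raise np.linalg.LinAlgError(
                    f"FᵀF is singular (rank {rank} < K={K}); use fewer feature "
                    "dimensions or a ridge penalty"
                )
        self.weights_ = np.linalg.solve(G, Fc.T @ (r - self.mean_rate_))
        self.n_features_in_ = K
        return self

    def predict(self, F: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return (
            (np.asarray(F, dtype=float) - self.feature_mean_) @ self.weights_
            + self.mean_rate_
        )


def _sst_floor(y: np.ndarray) -> float:
    # SST below float rounding noise of the response scale counts as zero
    return 1e-20 * max(1.0, float(np.sum(np.asarray(y) ** 2)))


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    """R² = 1 - SSE/SST with SST about the evaluation-set mean; 0/0 -> 0."""
    y = np.asarray(y, dtype=float)
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= _sst_floor(y):
        return 0.0
    return 1.0 - sse / sst


def train_test_split_ids(
    n: int, test_frac: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic disjoint train/test index split (default 90/10)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_frac)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def fit_axis(
    r: np.ndarray,
    F: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    ridge: float = 0.0,
    center_features: bool = True,
    window_ms=None,
    category=None,
    cell_id=None,
) -> PreferredAxis:
    """Fit one cell's preferred axis on the training stimuli, test on held-out.

    ``r`` holds per-stimulus mean rates, ``F`` the matching feature rows.
    Degenerate (constant) responses yield zero weights and R² = 0.
    """
    train_ids = np.asarray(train_ids)
    test_ids = np.asarray(test_ids)
    if np.intersect1d(train_ids, test_ids).size:
        raise ValueError("train and test ids overlap")
    model = PreferredAxisModel(ridge=ridge, center_features=center_features).fit(
        F[train_ids], r[train_ids]
    )
    r2_train = _r2(r[train_ids], model.predict(F[train_ids]))
    r2_test = _r2(r[test_ids], model.predict(F[test_ids]))
    return PreferredAxis(
        weights=model.weights_,
        mean_rate=model.mean_rate_,
        r2_train=r2_train,
        r2_test=r2_test,
        window_ms=window_ms,
        category=category,
        cell_id=cell_id,
        feature_mean=model.feature_mean_,
    )


def fit_axes_population(
    R: np.ndarray,
    F: np.ndarray,
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    ridge: float = 0.0,
    center_features: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized axis fit for all cells sharing one stimulus set and split.

    ``R`` is (cells, stimuli).  Returns ``(weights, mean_rates, r2_train,
    r2_test)`` with weights of shape (cells, K).  Identical to per-cell
    :func:`fit_axis` since the design matrix is shared.
    """
    R = np.asarray(R, dtype=float)
    fbar = F[train_ids].mean(axis=0) if center_features else 0.0
    Ftr, Fte = F[train_ids] - fbar, F[test_ids] - fbar
    K = F.shape[1]
    G = Ftr.T @ Ftr
    if ridge > 0:
        G = G + ridge * np.eye(K)
    elif np.linalg.matrix_rank(G) < K:
        raise np.linalg.LinAlgError(
            f"FᵀF is singular for K={K}; use fewer dimensions or a ridge penalty"
        )
    rbar = R[:, train_ids].mean(axis=1)
    W = np.linalg.solve(G, Ftr.T @ (R[:, train_ids] - rbar[:, None]).T).T  # (cells, K)

    def r2_block(idx, Fm):
        pred = W @ Fm.T + rbar[:, None]
        y = R[:, idx]
        sse = np.sum((y - pred) ** 2, axis=1)
        sst = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
        floor = 1e-20 * np.maximum(1.0, np.sum(y**2, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 1.0 - sse / sst
        return np.where(sst <= floor, 0.0, out)

    return W, rbar, r2_block(train_ids, Ftr), r2_block(test_ids, Fte)


def cross_predict(
    axis: PreferredAxis, r: np.ndarray, F: np.ndarray, test_ids: np.ndarray
) -> float:
    """R² of one category's axis predicting responses on another test set.

    May be strongly negative when the axes genuinely differ.
    """
    if F.shape[1] != len(axis.weights):
        raise ValueError("axis and feature space dimensions do not match")
    test_ids = np.asarray(test_ids)
    return _r2(r[test_ids], axis.predict(F[test_ids]))


def normalized_fo_correlation(
    r: np.ndarray,
    F: np.ndarray,
    category: np.ndarray,
    n_splits: int = 20,
    seed: int = 0,
    ridge: float = 0.0,
    min_upper: float = 0.1,
    return_upper: bool = False,
):
    """Face-object axis correlation normalized by its split-half upper bound.

    The raw correlation is the cosine between the face axis (fit on all face
    stimuli) and the object axis (fit on all object stimuli).  The upper bound
    imposed by out-of-distribution generalization is the mean over ``n_splits``
    resampled disjoint half-splits of the within-category axis correlations
    (face-half vs face-half, object-half vs object-half).  Cells whose upper
    bound falls below ``min_upper`` are too noisy to normalize (a pure-noise
    cell has an upper bound near 0) and return NaN.
    """
    r = np.asarray(r, dtype=float)
    category = np.asarray(category)
    face = category == "face"
    obj = ~face
    if face.sum() < 4 or obj.sum() < 4:
        raise ValueError("need at least 4 stimuli per category for split halves")

    def _axis(idx):
        model = PreferredAxisModel(ridge=ridge).fit(F[idx], r[idx])
        return model.weights_

    w_face = _axis(np.flatnonzero(face))
    w_obj = _axis(np.flatnonzero(obj))
    raw = cosine(w_face, w_obj)

    rng = np.random.default_rng(seed)
    uppers = []
    for m in (face, obj):
        idx = np.flatnonzero(m)
        half = len(idx) // 2
        for _ in range(n_splits):
            perm = rng.permutation(idx)
            uppers.append(cosine(_axis(perm[:half]), _axis(perm[half : 2 * half])))
    upper = float(np.nanmean(uppers))
    score = raw / upper if upper >= min_upper else float("nan")
    if return_upper:
        return score, upper
    return score


def artificial_unit_control(
    F: np.ndarray,
    category: np.ndarray,
    n_units: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    selectivity: str = "random",
    n_splits: int = 10,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """Run the axis pipeline on units that are exact linear functionals.

    Constructed units respond as ``r = F w (+ noise)`` and therefore have a
    single encoding axis by construction; their face and object axes must come
    out correlated, ruling out out-of-distribution generalization failure as an
    explanation for divergent axes in real populations.  ``selectivity='face'``
    biases the generating weights toward the leading (detection) dimensions so
    units are face-selective like the real comparison set.
    """
    F = np.asarray(F, dtype=float)
    category = np.asarray(category)
    rng = np.random.default_rng(seed)
    K = F.shape[1]
    W = rng.standard_normal((n_units, K))
    if selectivity == "face":
        W[:, :2] = np.abs(W[:, :2]) + 1.0
    rows = []
    face = category == "face"
    for u in range(n_units):
        r = F @ W[u]
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=len(r))
        tr_f, te_f = train_test_split_ids(face.sum(), seed=seed + 11)
        tr_o, te_o = train_test_split_ids((~face).sum(), seed=seed + 13)
        f_idx, o_idx = np.flatnonzero(face), np.flatnonzero(~face)
        ax_f = fit_axis(r[f_idx], F[f_idx], tr_f, te_f, ridge=ridge, category="face")
        ax_o = fit_axis(r[o_idx], F[o_idx], tr_o, te_o, ridge=ridge, category="object")
        nfo = normalized_fo_correlation(
            r, F, category, n_splits=n_splits, seed=seed + u, ridge=ridge
        )
        rows.append(
            {
                "unit": u,
                "r2_test_face": ax_f.r2_test,
                "r2_test_object": ax_o.r2_test,
                "cross_r2_face_on_object": cross_predict(ax_f, r[o_idx], F[o_idx], te_o),
                "cross_r2_object_on_face": cross_predict(ax_o, r[f_idx], F[f_idx], te_f),
                "raw_fo_cosine": cosine(ax_f.weights, ax_o.weights),
                "normalized_fo_correlation": nfo,
            }
        )
    return pd.DataFrame(rows)


def effectiveness_subsets(
    pop,
    k: int,
    window: tuple[float, float] = (50.0, 220.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Most-effective non-face and least-effective face stimuli.

    Stimuli are ranked by the population-mean response over ``window``; the
    top-``k`` non-face and bottom-``k`` face stimuli are returned with the
    ratio of their population-mean responses.  Used by the response-magnitude
    control: the non-face subset drives stronger responses yet must not
    trigger the reversal signature.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mean_resp = pop.window_mean(window).mean(axis=0)  # per stimulus
    face = pop.mask("face")
    obj_idx = np.flatnonzero(~face)
    face_idx = np.flatnonzero(face)
    if k > len(obj_idx) or k > len(face_idx):
        raise ValueError("k exceeds a category size")
    top_obj = obj_idx[np.argsort(-mean_resp[obj_idx], kind="stable")[:k]]
    bottom_face = face_idx[np.argsort(mean_resp[face_idx], kind="stable")[:k]]
    ratio = float(mean_resp[top_obj].mean() / mean_resp[bottom_face].mean())
    ids = pop.ids if pop.ids is not None else np.arange(pop.n_stimuli)
    return ids[top_obj], ids[bottom_face], ratio


def shuffle_control_r2(
    R: np.ndarray,
    F: np.ndarray,
    seed: int = 0,
    test_frac: float = 0.1,
    ridge: float = 0.0,
) -> np.ndarray:
    """Held-out R² per cell after shuffling stimulus labels.

    Permuting the correspondence between responses and features destroys any
    genuine axis tuning, so the expected test R² is near zero (slightly
    negative on average).
    """
    R = np.asarray(R, dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(R.shape[1])
    tr, te = train_test_split_ids(R.shape[1], test_frac=test_frac, seed=seed + 1)
    _, _, _, r2_test = fit_axes_population(R[:, perm], F, tr, te, ridge=ridge)
    return r2_test
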