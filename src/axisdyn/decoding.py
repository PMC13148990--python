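"""Window-wise linear decoding of latent stimulus features and identification.

Latent feature vectors are linearly decoded from population responses in
three equal-duration windows (short, long, combined), each made of two
sub-windows whose responses are stacked as if from distinct cells.  Decoded
latents are identified by nearest-neighbor matching against reference latents
(optionally in a linear metric space).  Cross-window transfer, accuracy as a
function of cell count, the redundancy-vs-diversity simulated-unit
experiment, and the categorization/discrimination PSI time courses quantify
what the late code switch buys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.linear_model import Ridge
from sklearn.utils.validation import check_is_fitted

from .axis_model import train_test_split_ids

__all__ = [
    "WindowSpec",
    "default_window_specs",
    "LatentDecoder",
    "stack_window_responses",
    "train_decoder",
    "cross_window_decode",
    "identify",
    "accuracy_vs_cellcount",
    "simulated_unit_experiment",
    "crossover_ordering",
    "categorization_discrimination_timecourse",
]


@dataclass(frozen=True)
class WindowSpec:
    """A named decoding window made of exactly two [start, end) sub-windows."""

    name: str
    sub_windows: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        if len(self.sub_windows) != 2:
            raise ValueError("a WindowSpec needs exactly two sub-windows")

    @property
    def duration(self) -> float:
        return sum(e - s for s, e in self.sub_windows)


def default_window_specs(offset_ms: float = 0.0) -> dict[str, WindowSpec]:
    """Short / long / combined decoding windows (equal total duration).

    ``offset_ms`` shifts all windows, e.g. +20 ms for the anterior (AM) face
    patch whose dynamics lag the middle-lateral (ML) patch.
    """

    def w(a, b):
        return (a + offset_ms, b + offset_ms)

    return {
        "short": WindowSpec("short", (w(50, 75), w(75, 100))),
        "long": WindowSpec("long", (w(120, 145), w(145, 170))),
        "combined": WindowSpec("combined", (w(62, 87), w(132, 157))),
    }


def stack_window_responses(
    pop, spec: WindowSpec, cell_idx: np.ndarray | None = None
) -> np.ndarray:
    """Stimuli x (2 x cells) matrix of sub-window mean rates.

    Responses from the two sub-windows are treated as if from distinct cells
    (stacking order: sub-window 1 cells, then sub-window 2 cells), letting a
    decoder assign distinct axes to each sub-window.
    """
    blocks = []
    for win in spec.sub_windows:
        M = pop.window_mean(win)
        if cell_idx is not None:
            M = M[cell_idx]
        blocks.append(M.T)  # (stim, cells)
    return np.concatenate(blocks, axis=1)


class LatentDecoder(BaseEstimator):
    """Ridge decoder from stacked population responses to latent features.

    The ridge penalty is selected on a held-out validation fold of the
    training stimuli, then the decoder is refit on the full training set.

    Attributes
    ----------
    model_ : sklearn Ridge, fitted
    alpha_ : selected penalty
    window : WindowSpec the decoder was trained on
    """

    def __init__(
        self,
        alphas: tuple[float, ...] = (1e-2, 1e-1, 1.0, 10.0, 100.0),
        val_frac: float = 0.2,
        seed: int = 0,
    ):
        self.alphas = alphas
        self.val_frac = val_frac
        self.seed = seed

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "LatentDecoder":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        fit_idx, val_idx = train_test_split_ids(
            len(X), test_frac=self.val_frac, seed=self.seed
        )
        best = (None, -np.inf)
        for a in self.alphas:
            m = Ridge(alpha=a).fit(X[fit_idx], Y[fit_idx])
            score = m.score(X[val_idx], Y[val_idx])
            if score > best[1]:
                best = (a, score)
        self.alpha_ = best[0]
        self.val_score_ = best[1]
        self.model_ = Ridge(alpha=self.alpha_).fit(X, Y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    def score(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Overall R² (uniform average over latent dimensions)."""
        check_is_fitted(self, "model_")
        return float(self.model_.score(X, Y))


def train_decoder(
    pop,
    latents: np.ndarray,
    window: WindowSpec,
    train_ids: np.ndarray,
    cell_idx: np.ndarray | None = None,
    **decoder_kwargs,
) -> LatentDecoder:
    """Fit a LatentDecoder on one window's stacked training responses."""
    X = stack_window_responses(pop, window, cell_idx)
    dec = LatentDecoder(**decoder_kwargs).fit(X[train_ids], latents[train_ids])
    dec.window = window
    dec.cell_idx = cell_idx
    return dec


def cross_window_decode(
    decoder: LatentDecoder,
    pop,
    other_window: WindowSpec,
    test_ids: np.ndarray,
    latents: np.ndarray | None = None,
):
    """Apply a trained decoder to responses from a different window.

    Returns decoded latents; with reference ``latents`` supplied, also the
    overall and per-dimension R² (which can be strongly negative when the
    neural code differs between windows).
    """
    X = stack_window_responses(pop, other_window, decoder.cell_idx)
    if X.shape[1] != decoder.n_features_in_:
        raise ValueError("cell count mismatch between decoder and population")
    decoded = decoder.predict(X[test_ids])
    if latents is None:
        return decoded
    Y = latents[test_ids]
    sse = np.sum((Y - decoded) ** 2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_dim = np.where(sst == 0, 0.0, 1.0 - sse / sst)
    return decoded, float(per_dim.mean()), per_dim


def identify(
    decoded: np.ndarray,
    reference: np.ndarray,
    metric_map: np.ndarray | None = None,
) -> float:
    """Nearest-neighbor identification accuracy of decoded latents.

    Item *i* is correct when its decoded vector is closer (Euclidean,
    optionally after a linear ``metric_map``) to reference *i* than to any
    other reference.  Ties resolve to the lowest stimulus index.
    """
    decoded = np.asarray(decoded, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference set")
    if metric_map is not None:
        decoded = decoded @ metric_map
        reference = reference @ metric_map
    d = cdist(decoded, reference)
    pred = np.argmin(d, axis=1)  # argmin takes the first minimum: lowest index
    return float(np.mean(pred == np.arange(len(decoded))))


def accuracy_vs_cellcount(
    pop,
    latents: np.ndarray,
    windows: dict[str, WindowSpec],
    cell_counts: tuple[int, ...] = (5, 10, 25, 50, 100),
    n_resample: int = 30,
    seed: int = 0,
    test_frac: float = 0.1,
    category: str = "face",
    metric_map: np.ndarray | None = None,
) -> pd.DataFrame:
    """Identification accuracy per window as a function of cell count.

    For each window and cell count, cells are randomly resampled
    ``n_resample`` times; each resample trains a decoder on the training
    stimuli and identifies the held-out stimuli among themselves.
    """
    if max(cell_counts) > pop.n_cells:
        raise ValueError("cell count exceeds population size")
    stim_idx = np.flatnonzero(pop.mask(category))
    tr, te = train_test_split_ids(len(stim_idx), test_frac=test_frac, seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    Y = latents[stim_idx]
    for name, spec in windows.items():
        Xfull = stack_window_responses(pop, spec)[stim_idx]
        n_cells = pop.n_cells
        for count in cell_counts:
            accs = []
            for _ in range(n_resample):
                if count == 0:
                    # no cells: decode the training mean for every stimulus
                    decoded = np.tile(Y[tr].mean(axis=0), (len(te), 1))
                    accs.append(identify(decoded, Y[te], metric_map))
                    continue
                cells = rng.choice(n_cells, size=count, replace=False)
                cols = np.concatenate([cells, cells + n_cells])
                X = Xfull[:, cols]
                dec = LatentDecoder(seed=seed).fit(X[tr], Y[tr])
                accs.append(identify(dec.predict(X[te]), Y[te], metric_map))
            accs = np.asarray(accs)
            rows.append(
                {
                    "window": name,
                    "n_cells": count,
                    "accuracy": accs.mean(),
                    "sem": accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def _decaying_latents(rng, n_stim: int, latent_dim: int) -> np.ndarray:
    # variance ~ 1/k across latent dimensions, as in PCA of deep-net features
    sds = 1.0 / np.sqrt(np.arange(1, latent_dim + 1))
    return rng.standard_normal((n_stim, latent_dim)) * sds


def simulated_unit_experiment(
    latent_dim: int = 60,
    low_dims: int = 5,
    noise_sd: float = 0.5,
    cell_counts: tuple[int, ...] = (5, 10, 25, 50, 100, 200),
    n_stim: int = 600,
    n_resample: int = 10,
    dims_per_unit: int = 5,
    seed: int = 0,
    test_frac: float = 0.15,
) -> pd.DataFrame:
    """Redundancy-vs-diversity trade-off with simulated linear units.

    "Short-latency" units each linearly combine a random subset of the first
    ``low_dims`` (high-variance) latent dimensions; "long-latency" units
    combine a random subset drawn from all ``latent_dim`` dimensions.  Both
    receive Gaussian noise.  Identification accuracy versus unit count shows
    the crossover: with few units the redundant low-dimensional code wins,
    with many units the diverse full-dimensional code wins.
    """
    if low_dims >= latent_dim:
        raise ValueError("low_dims must be smaller than latent_dim")
    rng = np.random.default_rng(seed)
    Z = _decaying_latents(rng, n_stim, latent_dim)
    tr, te = train_test_split_ids(n_stim, test_frac=test_frac, seed=seed)
    max_units = max(cell_counts)

    def make_units(dim_pool: np.ndarray) -> np.ndarray:
        R = np.empty((n_stim, max_units))
        for u in range(max_units):
            dims = rng.choice(dim_pool, size=min(dims_per_unit, len(dim_pool)), replace=False)
            w = rng.standard_normal(len(dims))
            R[:, u] = Z[:, dims] @ w + rng.normal(0.0, noise_sd, size=n_stim)
        return R

    responses = {
        "short": make_units(np.arange(low_dims)),
        "long": make_units(np.arange(latent_dim)),
    }
    rows = []
    for kind, R in responses.items():
        for count in cell_counts:
            accs = []
            for _ in range(n_resample):
                units = rng.choice(max_units, size=count, replace=False)
                dec = LatentDecoder(seed=seed).fit(R[tr][:, units], Z[tr])
                accs.append(identify(dec.predict(R[te][:, units]), Z[te]))
            accs = np.asarray(accs)
            rows.append(
                {
                    "window": kind,
                    "n_cells": count,
                    "accuracy": accs.mean(),
                    "sem": accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def crossover_ordering(curves: pd.DataFrame) -> dict:
    """Check the few-cells vs many-cells accuracy ordering between windows.

    Returns the short-minus-long accuracy difference at the smallest and
    largest cell counts and whether the crossover (short wins with few cells,
    long wins with many) holds.
    """
    short = curves[curves.window == "short"].set_index("n_cells").accuracy
    long_ = curves[curves.window == "long"].set_index("n_cells").accuracy
    counts = sorted(set(short.index) & set(long_.index))
    small, large = counts[0], counts[-1]
    d_small = float(short[small] - long_[small])
    d_large = float(short[large] - long_[large])
    return {
        "diff_small": d_small,
        "diff_large": d_large,
        "crossover": d_small > 0 and d_large < 0,
    }


def categorization_discrimination_timecourse(
    pop, windows: np.ndarray | None = None
) -> pd.DataFrame:
    """Category and identity PSI time courses from one population.

    Categorization: PSI between the face and object group means per window.
    Discrimination: PSI across individual face stimuli (each its own
    identity).  Face discrimination rising after the categorization peak is
    the signature of late-emerging identity tuning.
    """
    from .metrics import psi_timecourse

    cat = psi_timecourse(pop, "category", windows)
    ident = psi_timecourse(pop, "identity", windows)
    out = cat.rename(columns={"psi": "psi_category"})
    out["psi_identity"] = ident["psi"].to_numpy()
    return out
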