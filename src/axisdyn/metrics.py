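"""Population statistics: selectivity, sparseness, separation and change scores.

Implements the time-resolved face-selectivity d' and its 20-ms-window peak,
the face-selectivity index (FSI), the visual-responsiveness t-test, the
modified Treves-Rolls population sparseness, the population separation index
(PSI) for categorization/discrimination time courses, the
dimensions-for-90%-variance analysis, response-PC pseudo-units, and the
single-stimulus axis-change score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SelectivityRecord",
    "AxisChangeScore",
    "dprime_timecourse",
    "peak_dprime",
    "face_selectivity_index",
    "selectivity_record",
    "responsiveness_test",
    "sparseness",
    "sparseness_timecourse",
    "psi",
    "psi_timecourse",
    "dims_for_variance",
    "dims_comparison",
    "response_pc_pseudo_units",
    "axis_change_score",
]

DPRIME_CLIP = 10.0  # |d'| cap when variances vanish but means differ


@dataclass
class SelectivityRecord:
    """Per-cell selectivity summary."""

    dprime_t: np.ndarray  # per 1-ms bin
    peak_dprime: float
    fsi: float
    responsive_p: float


@dataclass
class AxisChangeScore:
    """Single-stimulus axis-change classification."""

    early_late_corr: np.ndarray  # per stimulus, Pearson across cells
    score: np.ndarray  # per stimulus, P(face | correlation)
    coef: float
    intercept: float
    included_cells: np.ndarray
    train_idx: np.ndarray


def dprime_timecourse(R_cell: np.ndarray, category: np.ndarray) -> np.ndarray:
    """Face-selectivity d' per 1-ms time bin.

    ``d'_t = (E(r_face,t) - E(r_object,t)) / sqrt((σ²_face,t + σ²_object,t)/2)``
    with means and variances taken over stimuli.  When both variances vanish,
    d' is 0 for equal means and clipped to ±10 otherwise.
    """
    R_cell = np.asarray(R_cell, dtype=float)  # (stimuli, T)
    category = np.asarray(category)
    face = category == "face"
    if face.sum() < 2 or (~face).sum() < 2:
        raise ValueError("need at least 2 stimuli per category")
    mf, mo = R_cell[face].mean(axis=0), R_cell[~face].mean(axis=0)
    vf = R_cell[face].var(axis=0, ddof=1)
    vo = R_cell[~face].var(axis=0, ddof=1)
    denom = np.sqrt(0.5 * (vf + vo))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (mf - mo) / denom
    zero_var = denom == 0
    d = np.where(zero_var & (mf == mo), 0.0, d)
    d = np.where(zero_var & (mf != mo), np.sign(mf - mo) * DPRIME_CLIP, d)
    return np.clip(d, -DPRIME_CLIP, DPRIME_CLIP)


def peak_dprime(
    dprime_t: np.ndarray,
    time_ms: np.ndarray,
    t_range: tuple[float, float] = (80.0, 120.0),
    width: float = 20.0,
) -> float:
    """Peak of the 20-ms sliding-window mean of d' with starts in ``t_range``.

    ``peak d' = max over T in [80, 120] of mean(d'_t, t in [T, T+20))``.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    best = -np.inf
    for T in np.arange(t_range[0], t_range[1] + 1e-9, 1.0):
        m = (time_ms >= T) & (time_ms < T + width)
        if m.sum() < width:
            break
        best = max(best, float(dprime_t[m].mean()))
    return best


def face_selectivity_index(
    R_cell: np.ndarray,
    category: np.ndarray,
    time_ms: np.ndarray,
    window: tuple[float, float] = (50.0, 220.0),
) -> float:
    """FSI = (r_face - r_nonface) / (r_face + r_nonface) over a 50-220 ms window."""
    m = (np.asarray(time_ms) >= window[0]) & (np.asarray(time_ms) < window[1])
    face = np.asarray(category) == "face"
    rf = R_cell[face][:, m].mean()
    rn = R_cell[~face][:, m].mean()
    if rf + rn == 0:
        return float("nan")
    return float((rf - rn) / (rf + rn))


def responsiveness_test(
    R_cell: np.ndarray,
    time_ms: np.ndarray,
    baseline_window: tuple[float, float] = (-50.0, 0.0),
    response_window: tuple[float, float] = (50.0, 300.0),
    paired: bool = True,
) -> float:
    """Two-sided t-test p-value comparing baseline and response activity.

    Per-stimulus mean rates in the two windows are compared; paired across
    stimuli by default (both windows come from the same presentations).
    Identical windows give p = 1.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    R_cell = np.asarray(R_cell, dtype=float)
    b = (time_ms >= baseline_window[0]) & (time_ms < baseline_window[1])
    r = (time_ms >= response_window[0]) & (time_ms < response_window[1])
    if not b.any() or not r.any():
        raise ValueError("baseline or response window not covered by the recording")
    base = R_cell[:, b].mean(axis=1)
    resp = R_cell[:, r].mean(axis=1)
    if paired:
        diff = resp - base
        if np.all(diff == diff[0]):
            if diff[0] == 0:
                return 1.0
            return 0.0 if len(diff) > 1 else 1.0
        t, p = stats.ttest_rel(resp, base)
    else:
        if resp.std() == 0 and base.std() == 0:
            return 1.0 if resp.mean() == base.mean() else 0.0
        t, p = stats.ttest_ind(resp, base)
    return float(p)


def selectivity_record(
    R_cell: np.ndarray, category: np.ndarray, time_ms: np.ndarray
) -> SelectivityRecord:
    """All per-cell selectivity statistics in one record."""
    d = dprime_timecourse(R_cell, category)
    return SelectivityRecord(
        dprime_t=d,
        peak_dprime=peak_dprime(d, time_ms),
        fsi=face_selectivity_index(R_cell, category, time_ms),
        responsive_p=responsiveness_test(R_cell, time_ms),
    )


def sparseness(r: np.ndarray) -> float:
    """Modified Treves-Rolls population sparseness of one population vector.

    ``S = 1 - (Σ_j r_j)² / (N Σ_j r_j²)`` for nonnegative rates across N
    cells; 0 for a uniform vector, 1 - 1/N for a one-hot vector, NaN when the
    vector is all zero.
    """
    r = np.asarray(r, dtype=float)
    ss = float(np.sum(r**2))
    if ss == 0:
        return float("nan")
    return float(1.0 - np.sum(r) ** 2 / (len(r) * ss))


def sparseness_timecourse(
    pop, smooth_ms: float | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Population sparseness per stimulus and time, plus category-mean curves.

    ``smooth_ms`` applies a boxcar of that width to each cell's rate time
    course first (standard PSTH smoothing); per-1-ms-bin trial noise otherwise
    dominates the statistic at realistic repeat counts.
    """
    R = pop.rates  # (cells, stim, T)
    if smooth_ms is not None:
        w = int(smooth_ms)
        kern = np.ones(w) / w
        R = np.apply_along_axis(lambda x: np.convolve(x, kern, "same"), 2, R)
    N = R.shape[0]
    tot = R.sum(axis=0)
    ss = (R**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = 1.0 - tot**2 / (N * ss)
    S = np.where(ss == 0, np.nan, S)  # (stim, T)
    means = {
        str(cat): np.nanmean(S[pop.category == cat], axis=0)
        for cat in np.unique(pop.category)
    }
    return S, means


def psi(R_window: np.ndarray, groups: np.ndarray) -> float:
    """Population separation index of one time window.

    Mean pairwise Euclidean distance between group-mean population vectors,
    divided by the pooled s.d. of all responses in the window.  Unitless,
    invariant to scaling and to adding a constant rate to every response.
    """
    R_window = np.asarray(R_window, dtype=float)  # (cells, stimuli)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    means = np.stack([R_window[:, groups == g].mean(axis=1) for g in uniq])
    dists = pdist(means)
    sigma = R_window.std()
    if sigma == 0:
        raise ValueError("zero pooled response s.d.")
    return float(np.mean(dists) / sigma)


def psi_timecourse(
    pop, grouping: str | np.ndarray = "category", windows: np.ndarray | None = None
) -> pd.DataFrame:
    """PSI per sliding window for a grouping of the stimuli.

    ``grouping='category'`` uses the face/object labels (categorization);
    ``grouping='identity'`` treats each face stimulus as its own identity and
    restricts the analysis to faces (discrimination).  An explicit label array
    may also be passed.
    """
    from .dynamics import make_windows

    if windows is None:
        windows = make_windows()
    if isinstance(grouping, str):
        if grouping == "category":
            labels = pop.category
            stim_mask = np.ones(pop.n_stimuli, bool)
        elif grouping == "identity":
            stim_mask = pop.mask("face")
            labels = np.arange(int(stim_mask.sum()))
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
    else:
        labels = np.asarray(grouping)
        stim_mask = np.ones(pop.n_stimuli, bool)
    rows = []
    for win in windows:
        Rw = pop.window_mean(tuple(win))[:, stim_mask]
        rows.append({"window_start": win[0], "psi": psi(Rw, labels)})
    return pd.DataFrame(rows)


def _zscore_rows(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (M - mu) / sd


def dims_for_variance(R_window: np.ndarray, q: float = 0.90) -> int:
    """Number of PCs needed to explain a fraction ``q`` of response variance.

    PCA is performed on the z-scored (per cell, across stimuli) cells x
    stimuli matrix for the window; returns the smallest m with cumulative
    explained-variance ratio >= q.
    """
    Z = _zscore_rows(np.asarray(R_window, dtype=float))
    if not np.any(Z):
        raise ValueError("window has no response variance")
    s = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), compute_uv=False)
    ratios = s**2 / np.sum(s**2)
    return int(np.searchsorted(np.cumsum(ratios), q) + 1)


def dims_comparison(
    R_early: np.ndarray,
    R_late: np.ndarray,
    q: float = 0.90,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Bootstrap comparison of dimensionality between two windows.

    Stimuli are resampled with replacement (the same resample applied to both
    windows); reports point estimates, bootstrap s.d.s, the fraction of
    resamples in which the late window needs more dimensions, and a paired
    t-test across bootstrap samples.
    """
    rng = np.random.default_rng(seed)
    n_stim = R_early.shape[1]
    m_early = dims_for_variance(R_early, q)
    m_late = dims_for_variance(R_late, q)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, n_stim, size=n_stim)
        boots[b, 0] = dims_for_variance(R_early[:, idx], q)
        boots[b, 1] = dims_for_variance(R_late[:, idx], q)
    diff = boots[:, 1] - boots[:, 0]
    if np.all(diff == diff[0]):
        t, p = (np.inf * np.sign(diff[0]) if diff[0] else 0.0), (0.0 if diff[0] else 1.0)
    else:
        t, p = stats.ttest_rel(boots[:, 1], boots[:, 0])
    return {
        "m_early": m_early,
        "m_late": m_late,
        "boot_sd_early": float(boots[:, 0].std(ddof=1)),
        "boot_sd_late": float(boots[:, 1].std(ddof=1)),
        "frac_late_gt_early": float(np.mean(diff > 0)),
        "t": float(t),
        "p": float(p),
    }


def response_pc_pseudo_units(
    pop,
    F: np.ndarray,
    k_extremes: int = 5,
    n_pc: int = 2,
    avg_window: tuple[float, float] = (50.0, 220.0),
    windows: np.ndarray | None = None,
    split_seed: int = 0,
    ridge: float = 0.0,
) -> dict:
    """Treat leading response PCs as pseudo-units and track their axes.

    PCA is run on the time-averaged cells x stimuli response matrix; the PC
    weight vectors over cells define pseudo-units whose time-resolved
    "responses" are the projections of the population vector.  For each
    pseudo-unit, sliding face and object axes are fit and the top/bottom
    ``k_extremes`` stimuli by projection are returned per window.  A PC with
    (near-)zero variance is flagged as degenerate.
    """
    from .dynamics import make_windows, sliding_axes
    from .simulate import ResponseTensor

    if pop.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if windows is None:
        windows = make_windows()
    M = pop.window_mean(avg_window)  # (cells, stim)
    Mc = M - M.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    var_ratio = s**2 / np.sum(s**2)
    pcs = U[:, :n_pc].T  # (n_pc, cells)
    pseudo_rates = np.einsum("pc,cst->pst", pcs, pop.rates)
    pseudo = ResponseTensor(
        rates=pseudo_rates - pseudo_rates.min(),  # shift: sparseness-free use only
        time_ms=pop.time_ms,
        n_repeats=pop.n_repeats,
        category=pop.category,
        ids=pop.ids,
    )
    out = {"explained_variance_ratio": var_ratio[:n_pc], "degenerate": var_ratio[:n_pc] < 1e-12}
    per_pc = []
    ids = pop.ids if pop.ids is not None else np.arange(pop.n_stimuli)
    for p in range(n_pc):
        entry = {}
        for cat in ("face", "object"):
            tc = sliding_axes(
                pseudo, F, cat, windows=windows, split_seed=split_seed, ridge=ridge
            )
            stim_idx = np.flatnonzero(pop.category == cat)
            proj = F[stim_idx] @ tc.axes[:, p, :].T  # (stim_cat, n_w)
            order = np.argsort(-proj, axis=0, kind="stable")
            entry[cat] = {
                "timecourse": tc,
                "top_ids": ids[stim_idx][order[:k_extremes]].T,
                "bottom_ids": ids[stim_idx][order[-k_extremes:]].T,
            }
        per_pc.append(entry)
    out["per_pc"] = per_pc
    return out


def axis_change_score(
    pop,
    early_window: tuple[float, float] = (60.0, 80.0),
    late_window: tuple[float, float] = (100.0, 120.0),
    exclude_percentiles: tuple[float, float] = (1.0, 99.0),
    rate_window: tuple[float, float] = (50.0, 220.0),
    train_frac: float = 0.5,
    seed: int = 0,
) -> AxisChangeScore:
    """Single-stimulus axis-change score from early-vs-late rank reversal.

    Works on raw firing rates (no per-cell normalization).  Cells with extreme
    mean rates (outside the given percentile band over ``rate_window``) are
    excluded so large between-cell rate differences cannot mask rank changes.
    For each stimulus, the Pearson correlation between the early- and
    late-window population vectors is computed; a single-feature unregularized
    logistic regression (inverse-frequency class weights) maps correlations to
    face probabilities on a training split, and every stimulus is scored.
    Higher score = more "face-like" population dynamics (more negative
    early-late correlation).
    """
    mean_rate = pop.window_mean(rate_window).mean(axis=1)
    lo, hi = np.percentile(mean_rate, exclude_percentiles)
    included = (mean_rate >= lo) & (mean_rate <= hi)
    if included.sum() < 3:
        raise ValueError("fewer than 3 cells after extreme-rate exclusion")
    E = pop.window_mean(early_window)[included]
    L = pop.window_mean(late_window)[included]
    n_stim = pop.n_stimuli
    Ec = E - E.mean(axis=0)
    Lc = L - L.mean(axis=0)
    se, sl = Ec.std(axis=0), Lc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ec * Lc).mean(axis=0) / (se * sl)
    corr = np.where((se == 0) | (sl == 0), np.nan, corr)

    rng = np.random.default_rng(seed)
    ok = ~np.isnan(corr)
    perm = rng.permutation(np.flatnonzero(ok))
    n_train = max(2, int(round(train_frac * len(perm))))
    train_idx = perm[:n_train]
    y = (pop.category == "face").astype(int)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split lacks both categories")
    clf = LogisticRegression(C=np.inf, class_weight="balanced", max_iter=1000)
    clf.fit(corr[train_idx, None], y[train_idx])
    score = np.full(n_stim, np.nan)
    score[ok] = clf.predict_proba(corr[ok, None])[:, 1]
    return AxisChangeScore(
        early_late_corr=corr,
        score=score,
        coef=float(clf.coef_[0, 0]),
        intercept=float(clf.intercept_[0]),
        included_cells=np.flatnonzero(included),
        train_idx=train_idx,
    )
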