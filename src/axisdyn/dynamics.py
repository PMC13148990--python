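"""Sliding-window axis estimation and stimulus-gated reversal detection.

Axes are fit to window-mean responses on a grid of half-open [start,
start+width) ms windows with a train/test split held fixed across windows.
From the resulting axis time courses the module computes window x window
cosine-similarity matrices, the face-object alignment time course (the
diagonal of the (face, object) matrix), per-cell alignment to the trial-wide
object axis, flip detection in the PC1-PC2 plane, divergence timing, the
per-cell adaptive short-latency window, and the delayed-weak-response control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axis_model import cosine_rows, fit_axes_population, train_test_split_ids

__all__ = [
    "AxisTimecourse",
    "SimilarityMatrix",
    "FlipReport",
    "make_windows",
    "sliding_axes",
    "similarity_matrices",
    "alignment_to_overall_object_axis",
    "detect_flip",
    "divergence_times",
    "adaptive_short_window",
    "latency_split_control",
]


def make_windows(
    start: float = 0.0, stop: float = 300.0, width: float = 20.0, step: float | None = None
) -> np.ndarray:
    """Half-open [s, s+width) window grid; non-overlapping by default."""
    if step is None:
        step = width
    starts = np.arange(start, stop - width + 1e-9, step)
    return np.stack([starts, starts + width], axis=1)


@dataclass
class AxisTimecourse:
    """Per-window, per-cell preferred axes for one stimulus category."""

    windows: np.ndarray  # (n_windows, 2) ms
    axes: np.ndarray  # (n_windows, n_cells, K)
    r2_train: np.ndarray  # (n_windows, n_cells)
    r2_test: np.ndarray  # (n_windows, n_cells)
    category: str
    train_ids: np.ndarray
    test_ids: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_cells(self) -> int:
        return self.axes.shape[1]

    def window_index(self, window: tuple[float, float]) -> int:
        hits = np.flatnonzero(
            (self.windows[:, 0] == window[0]) & (self.windows[:, 1] == window[1])
        )
        if not hits.size:
            raise ValueError(f"window {window} not on the grid")
        return int(hits[0])


@dataclass
class SimilarityMatrix:
    """Windows x windows mean cosine similarity across cells."""

    values: np.ndarray  # (n_windows, n_windows)
    sem: np.ndarray
    pair_kind: tuple[str, str]
    windows: np.ndarray

    def diagonal_timecourse(self) -> tuple[np.ndarray, np.ndarray]:
        """Same-latency similarity values and their s.e.m. per window."""
        return np.diagonal(self.values).copy(), np.diagonal(self.sem).copy()


@dataclass
class FlipReport:
    """Per-cell axis-reversal classification in the PC1-PC2 plane."""

    flip_flag: np.ndarray  # (n_cells,) bool
    flip_time_ms: np.ndarray  # (n_cells,) NaN where no flip
    angle_deg: np.ndarray  # early-vs-late 2-D angle
    included: np.ndarray  # cells passing the R² inclusion rule
    flip_fraction: float
    threshold_deg: float


def sliding_axes(
    pop,
    F: np.ndarray,
    category: str,
    windows: np.ndarray | None = None,
    test_frac: float = 0.1,
    split_seed: int = 0,
    ridge: float = 0.0,
) -> AxisTimecourse:
    """Fit per-cell axes to window-mean responses over a sliding grid.

    The train/test split over the category's stimuli is drawn once and reused
    for every window so that window-to-window axis comparisons are not
    confounded by split variability.
    """
    if windows is None:
        windows = make_windows()
    windows = np.asarray(windows, dtype=float)
    mask = pop.mask(category)
    stim_idx = np.flatnonzero(mask)
    Fc = F[stim_idx]
    tr, te = train_test_split_ids(len(stim_idx), test_frac=test_frac, seed=split_seed)
    n_w = len(windows)
    K = F.shape[1]
    axes = np.empty((n_w, pop.n_cells, K))
    r2_tr = np.empty((n_w, pop.n_cells))
    r2_te = np.empty((n_w, pop.n_cells))
    for w, win in enumerate(windows):
        Rw = pop.window_mean(tuple(win))[:, stim_idx]
        W, _, r2a, r2b = fit_axes_population(Rw, Fc, tr, te, ridge=ridge)
        axes[w], r2_tr[w], r2_te[w] = W, r2a, r2b
    return AxisTimecourse(
        windows=windows,
        axes=axes,
        r2_train=r2_tr,
        r2_test=r2_te,
        category=category,
        train_ids=stim_idx[tr],
        test_ids=stim_idx[te],
    )


def _pair_similarity(
    tc_a: AxisTimecourse, tc_b: AxisTimecourse, cell_mask: np.ndarray | None
) -> SimilarityMatrix:
    if tc_a.windows.shape != tc_b.windows.shape or not np.allclose(
        tc_a.windows, tc_b.windows
    ):
        raise ValueError("window grids do not match")
    cells = np.arange(tc_a.n_cells) if cell_mask is None else np.flatnonzero(cell_mask)
    n_w = tc_a.n_windows
    values = np.empty((n_w, n_w))
    sem = np.empty((n_w, n_w))
    A = tc_a.axes[:, cells, :]
    B = tc_b.axes[:, cells, :]
    for i in range(n_w):
        cos = cosine_rows(A[i][None, :, :], B)  # (n_w, cells)
        values[i] = np.nanmean(cos, axis=1)
        n_ok = np.sum(~np.isnan(cos), axis=1)
        sem[i] = np.nanstd(cos, axis=1, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
    return SimilarityMatrix(
        values=values,
        sem=sem,
        pair_kind=(tc_a.category, tc_b.category),
        windows=tc_a.windows,
    )


def similarity_matrices(
    tc_face: AxisTimecourse,
    tc_obj: AxisTimecourse,
    cell_mask: np.ndarray | None = None,
) -> dict[tuple[str, str], SimilarityMatrix]:
    """Mean cosine-similarity matrices for (object, object), (face, face) and
    (face, object) axis pairs across latencies.

    The diagonal of the (face, object) matrix is the face-object alignment
    time course.
    """
    return {
        ("object", "object"): _pair_similarity(tc_obj, tc_obj, cell_mask),
        ("face", "face"): _pair_similarity(tc_face, tc_face, cell_mask),
        ("face", "object"): _pair_similarity(tc_face, tc_obj, cell_mask),
    }


def alignment_to_overall_object_axis(
    tc: AxisTimecourse, overall_axes: np.ndarray
) -> np.ndarray:
    """Cells x windows cosine between time-varying axes and trial-wide object axes.

    ``overall_axes`` is (n_cells, K), typically fit over 50-220 ms.  Rows can
    be sorted by face-selectivity d' for display.  Zero-norm axes yield NaN.
    """
    out = np.empty((tc.n_cells, tc.n_windows))
    for w in range(tc.n_windows):
        out[:, w] = cosine_rows(tc.axes[w], overall_axes)
    return out


def detect_flip(
    tc_face: AxisTimecourse,
    early_window: tuple[float, float] = (80.0, 100.0),
    late_window: tuple[float, float] = (120.0, 140.0),
    threshold_deg: float = 120.0,
    r2_threshold: float = 0.0,
) -> FlipReport:
    """Classify per-cell face-axis reversal in the first two feature dimensions.

    A cell flips when the angle between the 2-D projections of its early and
    late face axes exceeds ``threshold_deg`` and both windows pass the held-out
    R² inclusion rule.  ``flip_time_ms`` is the start of the first window whose
    2-D cosine to the early axis falls below cos(threshold_deg).
    """
    if tc_face.axes.shape[2] < 2:
        raise ValueError("need at least 2 feature dimensions for flip detection")
    ei = tc_face.window_index(early_window)
    li = tc_face.window_index(late_window)
    v_e = tc_face.axes[ei, :, :2]
    v_l = tc_face.axes[li, :, :2]
    cos_el = cosine_rows(v_e, v_l)
    angle = np.degrees(np.arccos(np.clip(cos_el, -1.0, 1.0)))
    included = (tc_face.r2_test[ei] > r2_threshold) & (
        tc_face.r2_test[li] > r2_threshold
    )
    flip = included & (angle > threshold_deg)

    cos_thr = np.cos(np.radians(threshold_deg))
    flip_time = np.full(tc_face.n_cells, np.nan)
    for c in np.flatnonzero(flip):
        cos_t = cosine_rows(tc_face.axes[:, c, :2], np.broadcast_to(v_e[c], (tc_face.n_windows, 2)))
        # search forward from the early window
        later = np.flatnonzero((np.arange(tc_face.n_windows) > ei) & (cos_t < cos_thr))
        if later.size:
            flip_time[c] = tc_face.windows[later[0], 0]
    n_inc = included.sum()
    frac = float(flip.sum() / n_inc) if n_inc else float("nan")
    return FlipReport(
        flip_flag=flip,
        flip_time_ms=flip_time,
        angle_deg=angle,
        included=included,
        flip_fraction=frac,
        threshold_deg=threshold_deg,
    )


def divergence_times(
    tc_face: AxisTimecourse, overall_obj_axes: np.ndarray, n_consecutive: int = 2
) -> np.ndarray:
    """First window where the face axis turns against the trial-wide object axis.

    Defined as the start of the first window whose cosine to the overall
    object axis is negative for ``n_consecutive`` consecutive windows; NaN for
    cells that never diverge.
    """
    align = alignment_to_overall_object_axis(tc_face, overall_obj_axes)
    out = np.full(tc_face.n_cells, np.nan)
    neg = align < 0
    for c in range(tc_face.n_cells):
        run = 0
        for w in range(tc_face.n_windows):
            run = run + 1 if neg[c, w] else 0
            if run >= n_consecutive:
                out[c] = tc_face.windows[w - n_consecutive + 1, 0]
                break
    return out


def adaptive_short_window(
    rate_t: np.ndarray,
    time_ms: np.ndarray,
    width: float = 20.0,
    step: float | None = None,
    baseline_window: tuple[float, float] = (-25.0, 25.0),
    n_sd: float = 2.0,
    sd_floor: float = 0.1,
    scan_stop: float = 300.0,
) -> tuple[float, float] | None:
    """Per-cell short-latency window: first 20-ms window >= 2 s.d. above baseline.

    ``rate_t`` is the cell's mean response time course (Hz per 1-ms bin).
    Scans windows forward from 0 ms; returns None when no window crosses the
    threshold.  A zero baseline s.d. is floored at ``sd_floor`` Hz to keep the
    threshold finite for silent baselines.
    """
    rate_t = np.asarray(rate_t, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    b0 = (time_ms >= baseline_window[0]) & (time_ms < baseline_window[1])
    if not b0.any():
        raise ValueError("baseline window not covered by the recording")
    mu = rate_t[b0].mean()
    sd = max(rate_t[b0].std(), sd_floor)
    thr = mu + n_sd * sd
    for start, end in make_windows(0.0, min(scan_stop, time_ms[-1] + 1), width, step):
        m = (time_ms >= start) & (time_ms < end)
        if m.sum() < width:
            break
        if rate_t[m].mean() >= thr:
            return (float(start), float(end))
    return None


def latency_split_control(
    r_face_early: np.ndarray,
    r_face_late: np.ndarray,
    F_face: np.ndarray,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """Effectiveness-split axis comparison for one cell (delayed-weak control).

    Face stimuli are split into the 50% most- and least-effective halves by
    the early-window response; face axes are fit separately on each half at
    both windows and the 4 x 4 cosine matrix returned.  Under true axis
    switching, the (most-effective early, most-effective late) cosine is
    negative; under the delayed-weak-response artifact it stays positive.
    """
    from .axis_model import PreferredAxisModel, cosine

    r_face_early = np.asarray(r_face_early, dtype=float)
    r_face_late = np.asarray(r_face_late, dtype=float)
    n = len(r_face_early)
    if n < 8:
        raise ValueError("need at least 8 face stimuli")
    order = np.argsort(-r_face_early, kind="stable")
    most, least = order[: n // 2], order[n - n // 2 :]

    def _axis(idx, r):
        return PreferredAxisModel(ridge=ridge).fit(F_face[idx], r[idx]).weights_

    axes = {
        ("most", "early"): _axis(most, r_face_early),
        ("most", "late"): _axis(most, r_face_late),
        ("least", "early"): _axis(least, r_face_early),
        ("least", "late"): _axis(least, r_face_late),
    }
    labels = list(axes)
    M = np.array([[cosine(axes[a], axes[b]) for b in labels] for a in labels])
    names = [f"{grp}_{win}" for grp, win in labels]
    return pd.DataFrame(M, index=names, columns=names)
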