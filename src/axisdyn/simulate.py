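"""Synthetic stimulus sets and neural populations with stimulus-gated axis switching.

The generator emulates the statistical structure assumed by the axis analyses:
category-structured stimulus embeddings (faces displaced from objects along the
leading embedding directions), cells whose firing rates are noisy rectified
linear projections of stimulus features onto time-varying preferred axes, an
early detection-aligned phase, an optional abrupt switch to a reversed-low-
dimension + novel-high-dimension face axis, fixed object axes throughout, and
per-cell gain/latency heterogeneity.  Matched no-switch control populations and
three "cell-intrinsic artifact" generators (magnitude modulation, delayed weak
responses, raised-threshold adaptation) are provided so that downstream
reversal detectors can be tested for specificity.

All randomness is driven by explicit integer seeds; identical seeds yield
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "StimulusSet",
    "SyntheticGroundTruth",
    "ResponseTensor",
    "make_stimulus_set",
    "make_switching_truth",
    "make_no_switch_truth",
    "simulate_population",
    "simulate_artifact_population",
    "threshold_model_responses",
    "response_kernel",
    "calibrate_gaussian_sd",
]

FACE = "face"
OBJECT = "object"


@dataclass
class StimulusSet:
    """A stimuli x D embedding matrix with per-stimulus category labels."""

    embeddings: np.ndarray  # (n_stimuli, D)
    category: np.ndarray  # (n_stimuli,) of {"face", "object"}
    ids: np.ndarray  # (n_stimuli,) unique identifiers

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.category = np.asarray(self.category)
        self.ids = np.asarray(self.ids)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("stimulus ids must be unique")
        for cat in np.unique(self.category):
            if (self.category == cat).sum() < 2:
                raise ValueError(f"category {cat!r} has fewer than 2 stimuli")

    @property
    def n_stimuli(self) -> int:
        return self.embeddings.shape[0]

    @property
    def n_dim(self) -> int:
        return self.embeddings.shape[1]

    def mask(self, category: str) -> np.ndarray:
        return self.category == category


@dataclass
class SyntheticGroundTruth:
    """Per-cell generating axes and response parameters of a simulated population.

    Axes live in the K-dimensional normalized feature space obtained by PCA of
    the stimulus embeddings.  ``early_axes`` drive all responses before
    ``switch_time_ms``; from the switch onward, face stimuli are routed onto
    ``late_face_axes`` while object stimuli stay on ``object_axes``.
    """

    early_axes: np.ndarray  # (n_cells, K)
    late_face_axes: np.ndarray  # (n_cells, K)
    object_axes: np.ndarray  # (n_cells, K)
    switch_time_ms: float
    gain: np.ndarray  # (n_cells,) Hz per feature-unit
    latency_ms: np.ndarray  # (n_cells,)
    baseline_hz: np.ndarray  # (n_cells,)
    noise_model: Literal["poisson", "gaussian"] = "gaussian"
    noise_sd: float = 0.0  # Hz per 1-ms bin, gaussian only
    seed: int = 0
    crossfade_ms: float = 0.0  # optional linear blend at the switch
    flip_dims: int = 0
    new_dims: int = 0

    def __post_init__(self) -> None:
        for name in ("early_axes", "late_face_axes", "object_axes"):
            a = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(np.linalg.norm(a, axis=1) == 0):
                raise ValueError(f"{name} contains a zero-norm axis")
            setattr(self, name, a)
        self.gain = np.asarray(self.gain, dtype=float)
        self.latency_ms = np.asarray(self.latency_ms, dtype=float)
        self.baseline_hz = np.asarray(self.baseline_hz, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.early_axes.shape[0]

    @property
    def n_dim(self) -> int:
        return self.early_axes.shape[1]


@dataclass
class ResponseTensor:
    """cells x stimuli x time firing rates (Hz, 1-ms bins), repeat-averaged."""

    rates: np.ndarray  # (n_cells, n_stimuli, T)
    time_ms: np.ndarray  # (T,) relative to stimulus onset
    n_repeats: int
    category: np.ndarray  # (n_stimuli,)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.category = np.asarray(self.category)
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, 1.0):
            raise ValueError("time_ms must be strictly increasing with 1-ms spacing")
        if self.rates.shape[1] != len(self.category):
            raise ValueError("stimulus dimension mismatch with category labels")

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[1]

    def time_index(self, t_ms: float) -> int:
        """Index of the bin whose left edge is ``t_ms``."""
        idx = int(np.searchsorted(self.time_ms, t_ms))
        if idx >= len(self.time_ms) or self.time_ms[idx] != t_ms:
            raise ValueError(f"time {t_ms} ms not on the recorded 1-ms grid")
        return idx

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Bin slice for a half-open [start, end) ms window."""
        start, end = window
        i0 = int(np.searchsorted(self.time_ms, start))
        i1 = int(np.searchsorted(self.time_ms, end))
        if i0 == i1:
            raise ValueError(f"window {window} is empty on the recorded grid")
        return slice(i0, i1)

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Mean rate per cell x stimulus over a [start, end) ms window."""
        return self.rates[:, :, self.window_slice(window)].mean(axis=2)

    def mask(self, category: str) -> np.ndarray:
        return self.category == category


def _embedding_sds(D: int, spectrum: str | np.ndarray) -> np.ndarray:
    """Per-dimension standard deviations of the synthetic embedding."""
    if isinstance(spectrum, str):
        if spectrum == "flat":
            return np.ones(D)
        if spectrum == "powerlaw":
            # variance ~ 1/k: mimics the decaying PCA spectrum of deep-net
            # embeddings, where leading dimensions carry most stimulus variance
            return 1.0 / np.sqrt(np.arange(1, D + 1))
        raise ValueError(f"unknown spectrum {spectrum!r}")
    sds = np.asarray(spectrum, dtype=float)
    if sds.shape != (D,) or np.any(sds <= 0):
        raise ValueError("spectrum must be a length-D vector of positive s.d.s")
    return sds


def make_stimulus_set(
    n_face: int,
    n_object: int,
    D: int,
    category_offset: float | np.ndarray = 4.0,
    seed: int = 0,
    spectrum: str | np.ndarray = "powerlaw",
) -> StimulusSet:
    """Draw a Gaussian stimulus set with faces displaced from objects.

    Embeddings are zero-mean Gaussian with per-dimension s.d. given by
    ``spectrum``; face rows are additionally shifted by ``category_offset`` so
    the face centroid is displaced along the leading embedding directions.  A
    scalar offset ``c`` is expanded to a shift of ``c`` on each of the first
    two dimensions.
    """
    if n_face < 2 or n_object < 2:
        raise ValueError("need at least 2 stimuli per category")
    if D < 2:
        raise ValueError("need at least 2 embedding dimensions")
    offset = np.asarray(category_offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("category_offset must be finite")
    if offset.ndim == 0:
        vec = np.zeros(D)
        vec[:2] = float(offset)
        offset = vec
    elif offset.shape != (D,):
        raise ValueError("category_offset must be a scalar or length-D vector")

    rng = np.random.default_rng(seed)
    sds = _embedding_sds(D, spectrum)
    X = rng.standard_normal((n_face + n_object, D)) * sds
    X[:n_face] += offset
    category = np.array([FACE] * n_face + [OBJECT] * n_object)
    ids = np.array(
        [f"face_{i:05d}" for i in range(n_face)]
        + [f"object_{i:05d}" for i in range(n_object)]
    )
    return StimulusSet(embeddings=X, category=category, ids=ids)


def _detection_loadings(
    rng: np.random.Generator, n_cells: int, flip_dims: int, style: str = "uniform"
) -> np.ndarray:
    # strictly positive loadings guarantee positive cosine with the population
    # detection direction (uniform positive vector on the first flip_dims dims);
    # "halfnormal" spreads loadings more widely across the detection dims,
    # giving a more diverse low-dimensional early code
    if style == "uniform":
        return rng.uniform(0.5, 1.5, size=(n_cells, flip_dims))
    if style == "halfnormal":
        return np.abs(rng.standard_normal((n_cells, flip_dims))) + 0.05
    raise ValueError(f"unknown loading style {style!r}")


def make_switching_truth(
    K: int,
    n_cells: int,
    flip_dims: int = 1,
    new_dims: int | None = None,
    seed: int = 0,
    switch_time_ms: float = 100.0,
    highdim_sd: float = 0.02,
    new_gain: float = 1.0,
    gain_range: tuple[float, float] = (4.0, 8.0),
    baseline_range: tuple[float, float] = (10.0, 20.0),
    base_latency_ms: float = 50.0,
    latency_jitter_ms: float = 20.0,
    noise_model: Literal["poisson", "gaussian"] = "gaussian",
    noise_sd: float = 0.0,
    loading_style: str = "uniform",
) -> SyntheticGroundTruth:
    """Ground truth for a population that reverses its face axis at the switch.

    Early axes load positively onto the first ``flip_dims`` dimensions (the
    detection direction) plus small random high-dimensional components; late
    face axes negate those loadings and draw fresh independent loadings on the
    next ``new_dims`` dimensions (novel tuning).  Object axes equal early axes
    throughout.  ``new_gain`` scales the norm of the novel component relative
    to the reversed component.
    """
    if new_dims is None:
        new_dims = K - flip_dims
    if flip_dims + new_dims > K:
        raise ValueError("flip_dims + new_dims must not exceed K")
    if flip_dims == 0 and new_dims == 0:
        raise ValueError(
            "degenerate truth (flip_dims = new_dims = 0); use make_no_switch_truth"
        )
    rng = np.random.default_rng(seed)
    early = np.zeros((n_cells, K))
    early[:, :flip_dims] = _detection_loadings(rng, n_cells, flip_dims, loading_style)
    if K > flip_dims and highdim_sd > 0:
        early[:, flip_dims:] = rng.normal(0.0, highdim_sd, size=(n_cells, K - flip_dims))
    early /= np.linalg.norm(early, axis=1, keepdims=True)

    late = early.copy()
    late[:, :flip_dims] *= -1.0
    if new_dims > 0:
        flip_norm = np.linalg.norm(early[:, :flip_dims], axis=1, keepdims=True)
        fresh = rng.standard_normal((n_cells, new_dims))
        fresh /= np.linalg.norm(fresh, axis=1, keepdims=True)
        late[:, flip_dims : flip_dims + new_dims] = fresh * flip_norm * new_gain
    late /= np.linalg.norm(late, axis=1, keepdims=True)

    return SyntheticGroundTruth(
        early_axes=early,
        late_face_axes=late,
        object_axes=early.copy(),
        switch_time_ms=switch_time_ms,
        gain=rng.uniform(*gain_range, size=n_cells),
        latency_ms=base_latency_ms + rng.uniform(0.0, latency_jitter_ms, size=n_cells),
        baseline_hz=rng.uniform(*baseline_range, size=n_cells),
        noise_model=noise_model,
        noise_sd=noise_sd,
        seed=seed,
        flip_dims=flip_dims,
        new_dims=new_dims,
    )


def make_no_switch_truth(K: int, n_cells: int, flip_dims: int = 1, **kwargs) -> SyntheticGroundTruth:
    """Matched control population whose late face axes equal the early axes."""
    truth = make_switching_truth(K, n_cells, flip_dims=flip_dims, **kwargs)
    return replace(
        truth,
        late_face_axes=truth.early_axes.copy(),
        new_dims=0,
    )


def response_kernel(
    t_ms: np.ndarray,
    rise_ms: float = 10.0,
    decay_ms: float = 40.0,
    sustained: float = 0.35,
) -> np.ndarray:
    """Transient-plus-sustained temporal kernel, gated at 0 and peak-normalized.

    A difference-of-exponentials transient (rise 10 ms, decay 40 ms) riding on
    a saturating sustained component of relative amplitude ``sustained``:
    visually driven inferotemporal cells respond with a sharp transient that
    settles to a sustained plateau for the remainder of the stimulus, rather
    than decaying to silence.  ``sustained=0`` gives the pure transient.
    """
    t_peak = np.log(decay_ms / rise_ms) * rise_ms * decay_ms / (decay_ms - rise_ms)
    peak = np.exp(-t_peak / decay_ms) - np.exp(-t_peak / rise_ms)

    def raw(t):
        doe = np.where(t >= 0, np.exp(-t / decay_ms) - np.exp(-t / rise_ms), 0.0)
        plateau = np.where(t >= 0, 1.0 - np.exp(-t / (2.0 * rise_ms)), 0.0)
        return (1.0 - sustained) * doe / peak + sustained * plateau

    # composite peak found on a fine grid around the transient peak
    grid_max = raw(np.linspace(0.0, 10.0 * decay_ms, 2001)).max()
    return raw(np.asarray(t_ms, dtype=float)) / grid_max


def _features_for(stimuli: StimulusSet, K: int, space=None) -> np.ndarray:
    if space is None:
        from .feature_space import fit_space

        space = fit_space(stimuli.embeddings, K)
    return space.transform(stimuli.embeddings)


def _expected_rates(
    stimuli: StimulusSet,
    truth: SyntheticGroundTruth,
    time_ms: np.ndarray,
    F: np.ndarray,
) -> np.ndarray:
    """Noiseless expected rate tensor (cells, stimuli, T), rectification deferred."""
    n_cells, T = truth.n_cells, len(time_ms)
    early_proj = F @ truth.early_axes.T  # (stim, cells)
    late_proj = F @ truth.late_face_axes.T
    obj_proj = F @ truth.object_axes.T
    kern = response_kernel(time_ms[None, :] - truth.latency_ms[:, None])  # (cells, T)

    face = stimuli.mask(FACE)
    # face-gated axis switch; objects keep the object axis throughout
    proj_t = np.empty((n_cells, stimuli.n_stimuli, T))
    pre = time_ms < truth.switch_time_ms
    if truth.crossfade_ms > 0:
        w = np.clip((time_ms - truth.switch_time_ms) / truth.crossfade_ms, 0.0, 1.0)
    else:
        w = (~pre).astype(float)
    face_proj_t = (
        early_proj.T[:, face, None] * (1.0 - w)[None, None, :]
        + late_proj.T[:, face, None] * w[None, None, :]
    )
    proj_t[:, face, :] = face_proj_t
    proj_t[:, ~face, :] = obj_proj.T[:, ~face, None]

    rates = (
        truth.baseline_hz[:, None, None]
        + truth.gain[:, None, None] * proj_t * kern[:, None, :]
    )
    return rates


def simulate_population(
    stimuli: StimulusSet,
    truth: SyntheticGroundTruth,
    T: int = 300,
    n_repeats: int = 5,
    t_start: float = -50.0,
    space=None,
) -> ResponseTensor:
    """Simulate a repeat-averaged rate tensor from a ground-truth population.

    The expected rate of cell *j* to stimulus *i* at time *t* is
    ``baseline_j + gain_j * <axis_j(t, category_i), f_i> * kernel(t - latency_j)``,
    rectified at 0.  ``f_i`` are the stimulus features in the K-dimensional
    normalized PCA space of the embeddings (fit internally unless ``space`` is
    given).  Gaussian trial noise is added per 1-ms bin and per repeat before
    rectification; Poisson noise draws per-bin spike counts with the rectified
    mean as intensity.  Repeats are averaged into ``rates``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if T < 250:
        raise ValueError("T must cover at least [0, 250) ms")
    K = truth.n_dim
    if K > stimuli.n_dim:
        raise ValueError(
            f"truth dimension K={K} exceeds embedding dimension D={stimuli.n_dim}"
        )
    time_ms = np.arange(t_start, float(T), 1.0)
    F = _features_for(stimuli, K, space)
    mu = _expected_rates(stimuli, truth, time_ms, F)

    rng = np.random.default_rng(truth.seed + 1)
    if truth.noise_model == "gaussian":
        if truth.noise_sd > 0:
            acc = np.zeros_like(mu)
            for _ in range(n_repeats):
                acc += np.maximum(
                    mu + rng.normal(0.0, truth.noise_sd, size=mu.shape), 0.0
                )
            rates = acc / n_repeats
        else:
            rates = np.maximum(mu, 0.0)
    elif truth.noise_model == "poisson":
        lam = np.maximum(mu, 0.0) * 1e-3  # expected counts per 1-ms bin
        # the sum of n_repeats Poisson(lam) draws is Poisson(n*lam): draw once
        counts = rng.poisson(lam * n_repeats)
        rates = counts / (n_repeats * 1e-3)
    else:
        raise ValueError(f"unknown noise model {truth.noise_model!r}")

    return ResponseTensor(
        rates=rates,
        time_ms=time_ms,
        n_repeats=n_repeats,
        category=stimuli.category.copy(),
        ids=stimuli.ids.copy(),
    )


def threshold_model_responses(
    axis: np.ndarray, features: np.ndarray, threshold: float = 0.0
) -> np.ndarray:
    """Rates of a single-axis model cell with a raised firing threshold.

    ``rate_i = max(0, <axis, f_i> - threshold)``.  Used by the adaptation
    control: thresholding a fixed axis must not reverse the fitted axis.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    proj = np.asarray(features, dtype=float) @ np.asarray(axis, dtype=float)
    return np.maximum(proj - threshold, 0.0)


def simulate_artifact_population(
    kind: Literal["magnitude", "delayed_weak", "threshold"],
    stimuli: StimulusSet,
    truth: SyntheticGroundTruth,
    T: int = 300,
    n_repeats: int = 5,
    t_start: float = -50.0,
    space=None,
    late_gain_factor: float = 0.3,
    max_delay_ms: float = 40.0,
    threshold_frac: float = 0.6,
    onset_ms: float = 110.0,
) -> ResponseTensor:
    """Single-axis populations emulating cell-intrinsic artifact scenarios.

    Every cell keeps its (early) axis throughout; no axis switch occurs.  The
    three scenarios perturb the response time course in ways that could be
    mistaken for a code switch:

    - ``magnitude``: response gain drops to ``late_gain_factor`` after
      ``onset_ms`` (strong transient, weak sustained response).
    - ``delayed_weak``: each stimulus's response is delayed in inverse
      proportion to its drive (weak stimuli up to ``max_delay_ms`` later), so
      weak responses persist after strong ones subside.
    - ``threshold``: a raised firing threshold (adaptation) is applied after
      ``onset_ms``, at ``threshold_frac`` of the median positive drive.

    A faithful reversal detector must report no flip for any of these.
    """
    K = truth.n_dim
    time_ms = np.arange(t_start, float(T), 1.0)
    F = _features_for(stimuli, K, space)
    proj = (F @ truth.early_axes.T).T  # (cells, stim)
    kern = response_kernel(time_ms[None, :] - truth.latency_ms[:, None])  # (cells, T)

    if kind == "magnitude":
        mod = np.where(time_ms >= onset_ms, late_gain_factor, 1.0)
        mu = (
            truth.baseline_hz[:, None, None]
            + truth.gain[:, None, None]
            * proj[:, :, None]
            * (kern * mod[None, :])[:, None, :]
        )
    elif kind == "delayed_weak":
        lo, hi = proj.min(axis=1, keepdims=True), proj.max(axis=1, keepdims=True)
        weakness = (hi - proj) / np.maximum(hi - lo, 1e-12)  # 0 strongest, 1 weakest
        delay = weakness * max_delay_ms  # (cells, stim)
        t_shift = (
            time_ms[None, None, :]
            - truth.latency_ms[:, None, None]
            - delay[:, :, None]
        )
        mu = truth.baseline_hz[:, None, None] + truth.gain[:, None, None] * proj[
            :, :, None
        ] * response_kernel(t_shift)
    elif kind == "threshold":
        drive = truth.gain[:, None, None] * proj[:, :, None] * kern[:, None, :]
        pos = drive[drive > 0]
        theta = threshold_frac * (np.median(pos) if pos.size else 0.0)
        theta_t = np.where(time_ms >= onset_ms, theta, 0.0)
        # the threshold clips the drive (not the baseline) at zero
        mu = truth.baseline_hz[:, None, None] + np.maximum(
            drive - theta_t[None, None, :], 0.0
        )
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")

    rng = np.random.default_rng(truth.seed + 2)
    if truth.noise_model == "gaussian" and truth.noise_sd > 0:
        acc = np.zeros_like(mu)
        for _ in range(n_repeats):
            acc += np.maximum(mu + rng.normal(0.0, truth.noise_sd, size=mu.shape), 0.0)
        rates = acc / n_repeats
    elif truth.noise_model == "poisson":
        lam = np.maximum(mu, 0.0) * 1e-3
        rates = rng.poisson(lam * n_repeats) / (n_repeats * 1e-3)
    else:
        rates = np.maximum(mu, 0.0)

    return ResponseTensor(
        rates=rates,
        time_ms=time_ms,
        n_repeats=n_repeats,
        category=stimuli.category.copy(),
        ids=stimuli.ids.copy(),
    )


def calibrate_gaussian_sd(
    stimuli: StimulusSet,
    truth: SyntheticGroundTruth,
    window: tuple[float, float] = (80.0, 100.0),
    n_repeats: int = 5,
    target_r2: float = 0.5,
    T: int = 300,
    t_start: float = -50.0,
    space=None,
    n_train: int | None = None,
) -> float:
    """Per-bin gaussian noise s.d. giving roughly ``target_r2`` held-out R².

    The window-mean of per-bin noise over ``w`` bins and ``n`` repeats has
    variance ``sd² / (w·n)``.  The held-out R² of an OLS axis fit with K
    regressors and ``n_train`` training stimuli is approximately
    ``1 - σ²(1 + K/n_train) / (s² + σ²)`` where ``s`` is the across-stimulus
    signal s.d. of the window-mean expected rate; solving for σ gives
    ``σ² = s² (1 - t) / (t + K/n_train)`` at target ``t``.  The
    population-median signal s.d. over face stimuli is used.  ``n_train``
    defaults to 90% of the face count (the default split).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    time_ms = np.arange(t_start, float(T), 1.0)
    F = _features_for(stimuli, truth.n_dim, space)
    mu = _expected_rates(stimuli, truth, time_ms, F)
    i0 = int(np.searchsorted(time_ms, window[0]))
    i1 = int(np.searchsorted(time_ms, window[1]))
    wmean = np.maximum(mu, 0.0)[:, :, i0:i1].mean(axis=2)
    face = stimuli.mask(FACE)
    signal_sd = np.median(wmean[:, face].std(axis=1))
    n_bins = i1 - i0
    if n_train is None:
        n_train = int(round(0.9 * face.sum()))
    t = target_r2
    noise_var = signal_sd**2 * (1.0 - t) / (t + truth.n_dim / n_train)
    return float(np.sqrt(noise_var * n_bins * n_repeats))
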