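"""Pipeline driver: simulate -> fit space -> metrics -> axes -> dynamics -> report.

``RunConfig`` collects every parameter that matters (seeds, window grids, K,
inclusion thresholds, area latency offsets); ``run_pipeline`` chains the
stages, writes each intermediate container, and records provenance (config
hash, package version, seeds) so a rerun with the same config reproduces the
numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axis_model import fit_axes_population, train_test_split_ids
from .dynamics import detect_flip, make_windows, similarity_matrices, sliding_axes
from .feature_space import fit_space
from .io import save_population, save_space
from .metrics import (
    axis_change_score,
    dprime_timecourse,
    peak_dprime,
    face_selectivity_index,
    responsiveness_test,
    sparseness_timecourse,
)
from .simulate import (
    calibrate_gaussian_sd,
    make_no_switch_truth,
    make_stimulus_set,
    make_switching_truth,
    simulate_population,
)

log = logging.getLogger("axisdyn")

__all__ = ["RunConfig", "select_cells", "cell_metrics", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of a full synthetic-population analysis run."""

    seed: int = 0
    scenario: str = "switching"  # or "no_switch"
    n_face: int = 400
    n_object: int = 400
    n_cells: int = 60
    D: int = 80
    K: int = 20
    category_offset: float = 4.0
    flip_dims: int = 1
    switch_time_ms: float = 100.0
    n_repeats: int = 5
    T: int = 300
    target_r2: float | None = 0.7  # gaussian noise calibration; None = noiseless
    window_width: float = 20.0
    window_step: float = 20.0
    alpha_responsive: float = 0.05
    min_peak_dprime: float = 0.2
    min_r2: float = 0.0
    area_offset_ms: float = 0.0  # +20 for the anterior (AM) patch
    early_window: tuple[float, float] = (80.0, 100.0)
    late_window: tuple[float, float] = (120.0, 140.0)
    flip_threshold_deg: float = 120.0
    run_decoding: bool = True
    decode_resamples: int = 5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["early_window"] = list(d["early_window"])
        d["late_window"] = list(d["late_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for k in ("early_window", "late_window"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cell_metrics(pop) -> pd.DataFrame:
    """Per-cell selectivity and responsiveness table used for inclusion."""
    rows = []
    for c in range(pop.n_cells):
        Rc = pop.rates[c]
        d = dprime_timecourse(Rc, pop.category)
        rows.append(
            {
                "cell": c,
                "responsive_p": responsiveness_test(Rc, pop.time_ms),
                "peak_dprime": peak_dprime(d, pop.time_ms),
                "fsi": face_selectivity_index(Rc, pop.category, pop.time_ms),
                "response_var": float(pop.window_mean((50.0, 220.0))[c].var()),
            }
        )
    return pd.DataFrame(rows)


def select_cells(
    metrics: pd.DataFrame,
    alpha_responsive: float | None = 0.05,
    min_peak_dprime: float | None = 0.2,
    min_r2: float | None = 0.0,
    r2_face: np.ndarray | None = None,
    r2_object: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Conjunction of inclusion rules; returns kept cell ids and attrition.

    Rules (each disabled by passing None): significant visual responsiveness,
    non-zero response variance, peak d' at threshold within 80-140 ms, and
    positive held-out R² for both the face and object axes.  The conjunction
    is order-free; the attrition table counts, per rule, the cells that fail
    it (cells can appear under several rules).
    """
    n = len(metrics)
    keep = np.ones(n, dtype=bool)
    attrition: dict[str, int] = {}
    rules: dict[str, np.ndarray] = {}
    if alpha_responsive is not None:
        rules["responsive"] = metrics["responsive_p"].to_numpy() < alpha_responsive
    rules["variance"] = metrics["response_var"].to_numpy() > 0
    if min_peak_dprime is not None:
        rules["dprime"] = metrics["peak_dprime"].to_numpy() >= min_peak_dprime
    if min_r2 is not None and r2_face is not None and r2_object is not None:
        rules["r2"] = (np.asarray(r2_face) > min_r2) & (np.asarray(r2_object) > min_r2)
    for name, ok in rules.items():
        attrition[name] = int((~ok).sum())
        keep &= ok
    if not keep.any():
        log.warning("no cells survive the inclusion rules")
    return np.flatnonzero(keep), attrition


def _simulate_stage(cfg: RunConfig):
    stimuli = make_stimulus_set(
        cfg.n_face, cfg.n_object, cfg.D, cfg.category_offset, seed=cfg.seed
    )
    maker = make_switching_truth if cfg.scenario == "switching" else make_no_switch_truth
    truth = maker(
        cfg.K,
        cfg.n_cells,
        flip_dims=cfg.flip_dims,
        seed=cfg.seed + 1,
        switch_time_ms=cfg.switch_time_ms,
    )
    space = fit_space(stimuli.embeddings, cfg.K, ids=stimuli.ids)
    if cfg.target_r2 is not None:
        sd = calibrate_gaussian_sd(
            stimuli, truth, n_repeats=cfg.n_repeats, target_r2=cfg.target_r2,
            T=cfg.T, space=space,
        )
        truth = dataclasses.replace(truth, noise_sd=sd)
    pop = simulate_population(
        stimuli, truth, T=cfg.T, n_repeats=cfg.n_repeats, space=space
    )
    return stimuli, truth, space, pop


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full analysis chain and write artifacts + summary.

    Stages: simulate, fit-space, per-cell metrics, inclusion, trial-wide and
    sliding-window axes, similarity matrices, flip detection, sparseness and
    axis-change score.  Any stage failure aborts with the stage name; partial
    outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        stimuli, truth, space, pop = _simulate_stage(config)
        save_population(outdir / "pop.h5", pop, stimuli, truth)
        save_space(outdir / "space.h5", space)
        F = space.transform(stimuli.embeddings)

        stage = "metrics"
        metrics = cell_metrics(pop)
        metrics.to_csv(outdir / "cell_metrics.csv", index=False)

        stage = "axes"
        face_idx = np.flatnonzero(pop.mask("face"))
        obj_idx = np.flatnonzero(pop.mask("object"))
        tr_f, te_f = train_test_split_ids(len(face_idx), seed=config.seed + 7)
        tr_o, te_o = train_test_split_ids(len(obj_idx), seed=config.seed + 8)
        R_inc = pop.window_mean((80.0, 140.0))
        _, _, _, r2f = fit_axes_population(R_inc[:, face_idx], F[face_idx], tr_f, te_f)
        _, _, _, r2o = fit_axes_population(R_inc[:, obj_idx], F[obj_idx], tr_o, te_o)
        included, attrition = select_cells(
            metrics,
            config.alpha_responsive,
            config.min_peak_dprime,
            config.min_r2,
            r2_face=r2f,
            r2_object=r2o,
        )

        stage = "dynamics"
        off = config.area_offset_ms
        windows = make_windows(0.0, config.T, config.window_width, config.window_step)
        tc_face = sliding_axes(pop, F, "face", windows, split_seed=config.seed + 7)
        tc_obj = sliding_axes(pop, F, "object", windows, split_seed=config.seed + 8)
        cell_mask = np.zeros(pop.n_cells, bool)
        cell_mask[included] = True
        sims = similarity_matrices(tc_face, tc_obj, cell_mask)
        align, align_sem = sims[("face", "object")].diagonal_timecourse()
        flips = detect_flip(
            tc_face,
            tuple(np.array(config.early_window) + off),
            tuple(np.array(config.late_window) + off),
            threshold_deg=config.flip_threshold_deg,
            r2_threshold=config.min_r2,
        )
        np.savetxt(outdir / "alignment_timecourse.csv",
                   np.column_stack([windows[:, 0], align, align_sem]),
                   delimiter=",", header="window_start_ms,face_object_cosine,sem",
                   comments="")

        stage = "score"
        S, s_means = sparseness_timecourse(pop)
        acs = axis_change_score(pop, seed=config.seed + 9)

        stage = "decode"
        crossover = None
        if config.run_decoding:
            from .decoding import (
                accuracy_vs_cellcount,
                crossover_ordering,
                default_window_specs,
            )

            specs = default_window_specs(config.area_offset_ms)
            latents = (stimuli.embeddings - space.mean_) @ space.components_.T
            counts = tuple(
                sorted({min(5, pop.n_cells), pop.n_cells})
            )
            curves = accuracy_vs_cellcount(
                pop,
                latents,
                {k: specs[k] for k in ("short", "long")},
                cell_counts=counts,
                n_resample=config.decode_resamples,
                seed=config.seed + 10,
            )
            curves.to_csv(outdir / "decoding_curves.csv", index=False)
            crossover = crossover_ordering(curves)

        stage = "summary"
        switch_idx = np.searchsorted(windows[:, 0], truth.switch_time_ms) - 1
        post = slice(switch_idx + 1, None)
        pre = (windows[:, 0] >= 50) & (windows[:, 1] <= 110)
        t_post = pop.time_ms >= truth.switch_time_ms + 10
        summary = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "seed": config.seed,
            "scenario": config.scenario,
            "n_cells_included": int(len(included)),
            "attrition": attrition,
            "flip_fraction": flips.flip_fraction,
            "median_flip_time_ms": float(np.nanmedian(flips.flip_time_ms))
            if np.any(flips.flip_flag)
            else None,
            "switch_time_true_ms": truth.switch_time_ms,
            "switch_time_error_ms": float(
                abs(np.nanmedian(flips.flip_time_ms) - truth.switch_time_ms)
            )
            if np.any(flips.flip_flag)
            else None,
            "decoding_crossover": crossover,
            "alignment_pre_switch": _safe_nanmean(align[pre]),
            "alignment_post_switch": _safe_nanmean(align[post]),
            "sparseness_face_post": float(np.nanmean(s_means["face"][t_post])),
            "sparseness_object_post": float(np.nanmean(s_means["object"][t_post])),
            "axis_change_auroc": _auroc(
                acs.score, pop.category == "face"
            ),
        }
        with open(outdir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        with open(outdir / "provenance.json", "w") as f:
            json.dump(
                {
                    "config": config.to_dict(),
                    "config_hash": config.config_hash(),
                    "version": __version__,
                },
                f,
                indent=2,
            )
        return summary
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err


def _safe_nanmean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    ok = ~np.isnan(x)
    return float(x[ok].mean()) if ok.any() else float("nan")


def _auroc(score: np.ndarray, label: np.ndarray) -> float:
    ok = ~np.isnan(score)
    s, y = score[ok], label[ok]
    if len(np.unique(y)) < 2:
        return float("nan")
    from scipy.stats import rankdata

    r = rankdata(s)
    n1 = y.sum()
    n0 = len(y) - n1
    return float((r[y.astype(bool)].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))
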