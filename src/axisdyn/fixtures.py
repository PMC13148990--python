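"""Deterministic mini-population fixtures for tests and worked examples.

Each fixture is a small, fully seeded scenario (stationary, switching,
no-switch control, and the three cell-intrinsic artifact generators) that
regenerates bit-identically from its registry entry.  ``regenerate_fixtures``
writes the containers plus a summary CSV of headline quantities so an
end-to-end rerun can be diffed against a previous one.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .dynamics import detect_flip, make_windows, sliding_axes
from .feature_space import fit_space
from .io import save_population
from .simulate import (
    make_no_switch_truth,
    make_stimulus_set,
    make_switching_truth,
    simulate_artifact_population,
    simulate_population,
)

__all__ = ["FIXTURE_REGISTRY", "build_fixture", "regenerate_fixtures"]

# name -> (scenario, seed); seeds are frozen: changing one regenerates exactly
# that fixture and no other
FIXTURE_REGISTRY: dict[str, tuple[str, int]] = {
    "mini-stationary": ("stationary", 101),
    "mini-switch": ("switching", 102),
    "mini-noswitch": ("no_switch", 103),
    "artifact-magnitude": ("magnitude", 104),
    "artifact-delayed-weak": ("delayed_weak", 105),
    "artifact-threshold": ("threshold", 106),
}

_N_CELLS = 20
_N_STIM = 30  # per category
_K = 8
_D = 16


def build_fixture(name: str):
    """Build one registered fixture; returns (pop, stimuli, truth, space)."""
    scenario, seed = FIXTURE_REGISTRY[name]
    stimuli = make_stimulus_set(_N_STIM, _N_STIM, _D, 3.0, seed=seed)
    space = fit_space(stimuli.embeddings, _K)
    common = dict(flip_dims=3, seed=seed + 1, highdim_sd=0.05)
    if scenario == "switching":
        truth = make_switching_truth(_K, _N_CELLS, **common)
    elif scenario in ("stationary", "no_switch"):
        truth = make_no_switch_truth(_K, _N_CELLS, **common)
    else:
        truth = make_no_switch_truth(_K, _N_CELLS, **common)
        pop = simulate_artifact_population(scenario, stimuli, truth, space=space)
        return pop, stimuli, truth, space
    pop = simulate_population(stimuli, truth, space=space)
    return pop, stimuli, truth, space


def fixture_summary(name: str) -> dict:
    """Headline quantities of one fixture (flip fraction, alignment signs)."""
    pop, stimuli, truth, space = build_fixture(name)
    F = space.transform(stimuli.embeddings)
    windows = make_windows(40.0, 220.0)
    tc = sliding_axes(pop, F, "face", windows, split_seed=0)
    flips = detect_flip(tc)
    return {
        "fixture": name,
        "n_cells": pop.n_cells,
        "n_stimuli": pop.n_stimuli,
        "flip_fraction": flips.flip_fraction,
        "mean_rate_hz": float(pop.rates.mean()),
    }


def regenerate_fixtures(outdir: str | Path) -> Path:
    """Write all registered fixtures and their summary CSV to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in FIXTURE_REGISTRY:
        pop, stimuli, truth, _ = build_fixture(name)
        save_population(outdir / f"{name}.h5", pop, stimuli, truth)
        rows.append(fixture_summary(name))
    pd.DataFrame(rows).to_csv(outdir / "fixture_summary.csv", index=False)
    return outdir
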