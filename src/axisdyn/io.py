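"""Container I/O: populations, feature spaces and configs on disk.

Populations (stimulus set + response tensor + optional ground truth) and
feature spaces are stored in an HDF5 container (or NPZ, selected by file
extension) with fixed dataset names; ground truth and headers travel as JSON
strings so every array container stays self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .feature_space import FeatureSpace
from .simulate import ResponseTensor, StimulusSet, SyntheticGroundTruth

__all__ = [
    "save_population",
    "load_population",
    "save_space",
    "load_space",
    "load_config",
    "dump_config",
]


def _truth_to_json(truth: SyntheticGroundTruth) -> str:
    d = dataclasses.asdict(truth)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return json.dumps(d)


def _truth_from_json(s: str) -> SyntheticGroundTruth:
    return SyntheticGroundTruth(**json.loads(s))


def save_population(
    path: str | Path,
    pop: ResponseTensor,
    stimuli: StimulusSet | None = None,
    truth: SyntheticGroundTruth | None = None,
) -> Path:
    """Write a population container (.h5/.hdf5 or .npz by extension)."""
    path = Path(path)
    cat = np.asarray(pop.category, dtype="S")
    ids = None if pop.ids is None else np.asarray(pop.ids, dtype="S")
    if path.suffix == ".npz":
        payload = {
            "rates": pop.rates,
            "time_ms": pop.time_ms,
            "n_repeats": np.array(pop.n_repeats),
            "category": cat,
        }
        if ids is not None:
            payload["ids"] = ids
        if stimuli is not None:
            payload["embeddings"] = stimuli.embeddings
        if truth is not None:
            payload["truth_json"] = np.array(_truth_to_json(truth))
        np.savez_compressed(path, **payload)
        return path
    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=pop.rates, compression="gzip", compression_opts=4)
        f.create_dataset("time_ms", data=pop.time_ms)
        f.attrs["n_repeats"] = pop.n_repeats
        f.create_dataset("category", data=cat)
        if ids is not None:
            f.create_dataset("ids", data=ids)
        if stimuli is not None:
            f.create_dataset("embeddings", data=stimuli.embeddings)
        if truth is not None:
            f.attrs["truth_json"] = _truth_to_json(truth)
    return path


def load_population(path: str | Path):
    """Read a population container; returns (pop, stimuli | None, truth | None)."""
    path = Path(path)

    def decode(a):
        return np.array([x.decode() for x in a])

    if path.suffix == ".npz":
        z = np.load(path, allow_pickle=False)
        cat = decode(z["category"])
        ids = decode(z["ids"]) if "ids" in z else None
        pop = ResponseTensor(
            rates=z["rates"],
            time_ms=z["time_ms"],
            n_repeats=int(z["n_repeats"]),
            category=cat,
            ids=ids,
        )
        stimuli = None
        if "embeddings" in z:
            stimuli = StimulusSet(
                embeddings=z["embeddings"],
                category=cat,
                ids=ids if ids is not None else np.arange(len(cat)).astype(str),
            )
        truth = _truth_from_json(str(z["truth_json"])) if "truth_json" in z else None
        return pop, stimuli, truth
    with h5py.File(path, "r") as f:
        cat = decode(f["category"][...])
        ids = decode(f["ids"][...]) if "ids" in f else None
        pop = ResponseTensor(
            rates=f["rates"][...],
            time_ms=f["time_ms"][...],
            n_repeats=int(f.attrs["n_repeats"]),
            category=cat,
            ids=ids,
        )
        stimuli = None
        if "embeddings" in f:
            stimuli = StimulusSet(
                embeddings=f["embeddings"][...],
                category=cat,
                ids=ids if ids is not None else np.arange(len(cat)).astype(str),
            )
        truth = (
            _truth_from_json(f.attrs["truth_json"]) if "truth_json" in f.attrs else None
        )
    return pop, stimuli, truth


def save_space(path: str | Path, space: FeatureSpace) -> Path:
    """Write a fitted feature space to an HDF5 (or NPZ) container."""
    path = Path(path)
    header = json.dumps(
        {
            "K": int(space.n_components),
            "fit_ids": None
            if space.fit_stimulus_ids_ is None
            else list(map(str, space.fit_stimulus_ids_)),
        }
    )
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            mean=space.mean_,
            components=space.components_,
            scale=space.scale_,
            explained_variance_ratio=space.explained_variance_ratio_,
            header=np.array(header),
        )
        return path
    with h5py.File(path, "w") as f:
        g = f.create_group("space")
        g.create_dataset("mean", data=space.mean_)
        g.create_dataset("components", data=space.components_)
        g.create_dataset("scale", data=space.scale_)
        g.create_dataset("explained_variance_ratio", data=space.explained_variance_ratio_)
        f.attrs["header"] = header
    return path


def load_space(path: str | Path) -> FeatureSpace:
    path = Path(path)
    if path.suffix == ".npz":
        z = np.load(path, allow_pickle=False)
        mean, comps, scale, evr = (
            z["mean"],
            z["components"],
            z["scale"],
            z["explained_variance_ratio"],
        )
        header = json.loads(str(z["header"]))
    else:
        with h5py.File(path, "r") as f:
            g = f["space"]
            mean, comps, scale, evr = (
                g["mean"][...],
                g["components"][...],
                g["scale"][...],
                g["explained_variance_ratio"][...],
            )
            header = json.loads(f.attrs["header"])
    space = FeatureSpace(n_components=int(header["K"]))
    space.mean_ = mean
    space.components_ = comps
    space.scale_ = scale
    space.explained_variance_ratio_ = evr
    space.n_features_in_ = comps.shape[1]
    space.fit_stimulus_ids_ = (
        None if header["fit_ids"] is None else np.asarray(header["fit_ids"])
    )
    return space


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)
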