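"""Shared synthetic fixtures: small populations with known generating axes."""

import dataclasses

import numpy as np
import pytest

import axisdyn as ad
from axisdyn.feature_space import fit_space

K = 12
D = 24
N_STIM = 120  # per category
N_CELLS = 25


@pytest.fixture(scope="session")
def stimset():
    return ad.make_stimulus_set(N_STIM, N_STIM, D, seed=11)


@pytest.fixture(scope="session")
def space(stimset):
    return fit_space(stimset.embeddings, K)


@pytest.fixture(scope="session")
def features(stimset, space):
    return space.transform(stimset.embeddings)


@pytest.fixture(scope="session")
def switching_truth():
    return ad.make_switching_truth(K, N_CELLS, seed=12)


@pytest.fixture(scope="session")
def noswitch_truth():
    return ad.make_no_switch_truth(K, N_CELLS, seed=12)


@pytest.fixture(scope="session")
def switching_pop(stimset, switching_truth, space):
    """Noiseless switching population: downstream fits are exact."""
    return ad.simulate_population(stimset, switching_truth, n_repeats=1, space=space)


@pytest.fixture(scope="session")
def noswitch_pop(stimset, noswitch_truth, space):
    return ad.simulate_population(stimset, noswitch_truth, n_repeats=1, space=space)


@pytest.fixture(scope="session")
def noisy_switching_pop(stimset, switching_truth, space):
    truth = dataclasses.replace(switching_truth, noise_sd=15.0)
    return ad.simulate_population(stimset, truth, n_repeats=5, space=space)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
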