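"""Generator contracts: stimulus sets, ground truths, response tensors, noise."""

import dataclasses

import numpy as np
import pytest

import axisdyn as ad
from axisdyn.simulate import (
    response_kernel,
    simulate_artifact_population,
    threshold_model_responses,
)


class TestMakeStimulusSet:
    def test_zero_offset_centroids_match(self):
        ss = ad.make_stimulus_set(400, 400, 8, category_offset=0.0, seed=1)
        f = ss.embeddings[ss.mask("face")].mean(axis=0)
        o = ss.embeddings[ss.mask("object")].mean(axis=0)
        assert np.allclose(f, o, atol=0.25)

    def test_offset_shifts_face_centroid(self):
        # law-of-large-numbers check on the sample mean difference
        off = np.zeros(60)
        off[0] = 3.0
        ss = ad.make_stimulus_set(1000, 1000, 60, off, seed=7, spectrum="flat")
        diff = (
            ss.embeddings[ss.mask("face"), 0].mean()
            - ss.embeddings[ss.mask("object"), 0].mean()
        )
        assert abs(diff - 3.0) < 0.2

    def test_deterministic_given_seed(self):
        a = ad.make_stimulus_set(20, 20, 6, seed=7)
        b = ad.make_stimulus_set(20, 20, 6, seed=7)
        assert np.array_equal(a.embeddings, b.embeddings)
        c = ad.make_stimulus_set(20, 20, 6, seed=8)
        assert not np.array_equal(a.embeddings, c.embeddings)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            ad.make_stimulus_set(1, 5, 6)
        with pytest.raises(ValueError):
            ad.make_stimulus_set(5, 5, 6, category_offset=np.nan)
        with pytest.raises(ValueError):
            ad.make_stimulus_set(5, 5, 6, category_offset=np.ones(3))

    def test_unique_ids_and_spectrum(self):
        ss = ad.make_stimulus_set(2000, 5, 10, seed=0)
        assert len(np.unique(ss.ids)) == 2005
        sds = ss.embeddings[ss.mask("object")].std(axis=0)
        # decaying spectrum: later dimensions carry less variance
        assert sds[0] > sds[-1]


class TestMakeSwitchingTruth:
    def test_full_reversal_without_jitter(self):
        t = ad.make_switching_truth(6, 10, flip_dims=6, new_dims=0, highdim_sd=0.0, seed=3)
        cos = np.sum(t.early_axes * t.late_face_axes, axis=1)
        assert np.allclose(cos, -1.0)

    def test_low_dim_reversal_signature(self):
        t = ad.make_switching_truth(60, 100, flip_dims=5, new_dims=55, seed=3)
        e, l = t.early_axes[:, :5], t.late_face_axes[:, :5]
        cos = np.sum(e * l, axis=1) / (
            np.linalg.norm(e, axis=1) * np.linalg.norm(l, axis=1)
        )
        assert cos.mean() < 0

    def test_detection_alignment_guarantee(self):
        t = ad.make_switching_truth(12, 50, flip_dims=3, seed=5)
        detection = np.zeros(12)
        detection[:3] = 1.0
        cos = t.early_axes @ detection / (
            np.linalg.norm(t.early_axes, axis=1) * np.linalg.norm(detection)
        )
        assert np.all(cos > 0)
        assert t.object_axes is not t.early_axes
        assert np.array_equal(t.object_axes, t.early_axes)

    def test_determinism_and_degenerate_rejection(self):
        a = ad.make_switching_truth(8, 5, seed=3)
        b = ad.make_switching_truth(8, 5, seed=3)
        assert np.array_equal(a.early_axes, b.early_axes)
        c = ad.make_switching_truth(8, 5, seed=4)
        assert not np.array_equal(a.early_axes, c.early_axes)
        with pytest.raises(ValueError):
            ad.make_switching_truth(8, 5, flip_dims=0, new_dims=0)
        with pytest.raises(ValueError):
            ad.make_switching_truth(8, 5, flip_dims=5, new_dims=5)


class TestSimulatePopulation:
    def test_noiseless_response_is_linear_in_features(self, stimset, space, features):
        truth = ad.make_switching_truth(12, 5, seed=2, baseline_range=(30.0, 40.0))
        pop = ad.simulate_population(stimset, truth, n_repeats=1, space=space)
        # pre-switch window: response = baseline + gain * <early, f> * kernel
        R = pop.window_mean((80.0, 100.0))
        for c in range(5):
            pred = features @ truth.early_axes[c]
            resid = np.corrcoef(pred[stimset.mask("face")], R[c, stimset.mask("face")])
            assert resid[0, 1] > 1 - 1e-10

    def test_reversal_flips_pre_post_correlation(self, switching_pop):
        f = switching_pop.mask("face")
        pre = switching_pop.window_mean((80.0, 100.0))[:, f]
        post = switching_pop.window_mean((120.0, 140.0))[:, f]
        pre_c = pre - pre.mean(axis=1, keepdims=True)
        post_c = post - post.mean(axis=1, keepdims=True)
        corr = (pre_c * post_c).sum(1) / (
            np.linalg.norm(pre_c, axis=1) * np.linalg.norm(post_c, axis=1)
        )
        assert np.median(corr) < 0

    def test_no_switch_control_keeps_correlation(self, noswitch_pop):
        f = noswitch_pop.mask("face")
        pre = noswitch_pop.window_mean((80.0, 100.0))[:, f]
        post = noswitch_pop.window_mean((120.0, 140.0))[:, f]
        pre_c = pre - pre.mean(axis=1, keepdims=True)
        post_c = post - post.mean(axis=1, keepdims=True)
        corr = (pre_c * post_c).sum(1) / (
            np.linalg.norm(pre_c, axis=1) * np.linalg.norm(post_c, axis=1)
        )
        assert np.all(corr > 0.99)

    def test_poisson_counts_have_unit_fano(self, stimset, space):
        truth = ad.make_switching_truth(
            12, 3, seed=6, noise_model="poisson", baseline_range=(10.0, 10.0)
        )
        n_rep = 200
        pop = ad.simulate_population(stimset, truth, n_repeats=n_rep, space=space)
        # baseline bins share the expected rate (10 Hz >= 5 Hz)
        base = pop.rates[:, :, pop.window_slice((-50.0, 0.0))]
        counts = base * 1e-3 * n_rep
        fano = counts.var() / counts.mean()
        assert 0.8 < fano < 1.2
        assert np.all(pop.rates >= 0)

    def test_determinism(self, stimset, space, switching_truth):
        a = ad.simulate_population(stimset, switching_truth, n_repeats=2, space=space)
        b = ad.simulate_population(stimset, switching_truth, n_repeats=2, space=space)
        assert np.array_equal(a.rates, b.rates)

    def test_rejects_bad_args(self, stimset, switching_truth):
        with pytest.raises(ValueError):
            ad.simulate_population(stimset, switching_truth, n_repeats=0)
        with pytest.raises(ValueError):
            ad.simulate_population(stimset, switching_truth, T=100)


class TestThresholdModel:
    def test_hand_example(self):
        F = np.array([[-1.0, 0.0], [0.5, 0.0], [2.0, 0.0]])
        rates = threshold_model_responses(np.array([1.0, 0.0]), F, threshold=1.0)
        assert np.allclose(rates, [0.0, 0.0, 1.0])

    def test_zero_threshold_is_rectified_projection(self, rng):
        F = rng.standard_normal((30, 4))
        ax = rng.standard_normal(4)
        assert np.allclose(
            threshold_model_responses(ax, F, 0.0), np.maximum(F @ ax, 0.0)
        )

    def test_saturating_threshold_silences(self, rng):
        F = rng.standard_normal((30, 4))
        ax = rng.standard_normal(4)
        thr = (F @ ax).max() + 1.0
        assert np.all(threshold_model_responses(ax, F, thr) == 0.0)


class TestKernelAndArtifacts:
    def test_kernel_gated_and_normalized(self):
        t = np.arange(-50.0, 300.0)
        k = response_kernel(t)
        assert np.all(k[t < 0] == 0)
        assert np.isclose(k.max(), 1.0)
        assert np.all(k >= 0)

    def test_artifact_kinds_run_and_keep_axis(self, stimset, space, noswitch_truth):
        for kind in ("magnitude", "delayed_weak", "threshold"):
            pop = simulate_artifact_population(
                kind, stimset, noswitch_truth, n_repeats=1, space=space
            )
            assert pop.rates.shape[0] == noswitch_truth.n_cells
        with pytest.raises(ValueError):
            simulate_artifact_population("bogus", stimset, noswitch_truth, space=space)


def test_calibration_hits_target_r2(stimset, space):
    from axisdyn.axis_model import fit_axes_population, train_test_split_ids
    from axisdyn.simulate import calibrate_gaussian_sd

    truth = ad.make_switching_truth(12, 40, seed=9)
    sd = calibrate_gaussian_sd(
        stimset, truth, window=(80.0, 100.0), n_repeats=5, target_r2=0.5, space=space
    )
    pop = ad.simulate_population(
        stimset, dataclasses.replace(truth, noise_sd=sd), n_repeats=5, space=space
    )
    f_idx = np.flatnonzero(stimset.mask("face"))
    tr, te = train_test_split_ids(len(f_idx), seed=1)
    F = space.transform(stimset.embeddings)
    R = pop.window_mean((80.0, 100.0))[:, f_idx]
    _, _, _, r2 = fit_axes_population(R, F[f_idx], tr, te)
    assert 0.3 < np.median(r2) < 0.7
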