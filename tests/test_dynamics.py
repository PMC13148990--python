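"""Sliding-window axis dynamics: similarity, flip detection, adaptive windows."""

import numpy as np
import pytest

from axisdyn.axis_model import cosine_rows
from axisdyn.dynamics import (
    AxisTimecourse,
    adaptive_short_window,
    alignment_to_overall_object_axis,
    detect_flip,
    divergence_times,
    latency_split_control,
    make_windows,
    similarity_matrices,
    sliding_axes,
)
from axisdyn.simulate import simulate_artifact_population


@pytest.fixture(scope="module")
def tc_pair(switching_pop, features):
    wins = make_windows(0.0, 300.0)
    tc_f = sliding_axes(switching_pop, features, "face", wins, split_seed=1)
    tc_o = sliding_axes(switching_pop, features, "object", wins, split_seed=2)
    return tc_f, tc_o


class TestSlidingAxes:
    def test_stationary_axes_stable_across_windows(self, noswitch_pop, features):
        wins = make_windows(80.0, 220.0)
        tc = sliding_axes(noswitch_pop, features, "face", wins, split_seed=0)
        for w in range(tc.n_windows - 1):
            cos = cosine_rows(tc.axes[w], tc.axes[w + 1])
            assert np.nanmin(cos) >= 0.99

    def test_switch_reverses_face_axis(self, tc_pair):
        tc_f, _ = tc_pair
        ei = tc_f.window_index((80.0, 100.0))
        li = tc_f.window_index((120.0, 140.0))
        cos = cosine_rows(tc_f.axes[ei], tc_f.axes[li])
        assert np.median(cos) < 0

    def test_pre_response_windows_flagged_low_r2(self, switching_pop, features):
        tc = sliding_axes(
            switching_pop, features, "face", make_windows(0.0, 40.0), split_seed=0
        )
        # before the earliest latency there is no signal to explain
        assert np.all(tc.r2_test <= 0.05)

    def test_empty_window_rejected(self, switching_pop, features):
        with pytest.raises(ValueError):
            sliding_axes(
                switching_pop, features, "face", np.array([[500.0, 520.0]])
            )


class TestSimilarityMatrices:
    def test_same_category_diagonal_is_one_and_symmetric(self, tc_pair):
        tc_f, tc_o = tc_pair
        sims = similarity_matrices(tc_f, tc_o)
        ff = sims[("face", "face")].values
        assert np.allclose(np.diag(ff), 1.0)
        assert np.allclose(ff, ff.T, atol=1e-12)
        assert np.nanmax(np.abs(ff)) <= 1 + 1e-12

    def test_face_object_diagonal_flips_sign_at_switch(self, tc_pair):
        tc_f, tc_o = tc_pair
        diag, sem = similarity_matrices(tc_f, tc_o)[("face", "object")].diagonal_timecourse()
        wins = tc_f.windows[:, 0]
        pre = (wins >= 60) & (wins < 100)
        post = (wins >= 100) & (wins < 200)
        assert np.all(diag[pre] > 0)
        assert np.all(diag[post] < 0)
        assert np.all(sem >= 0)

    def test_constructed_antiparallel_axes_give_minus_one(self):
        wins = make_windows(0.0, 40.0)
        axes = np.tile(np.random.default_rng(0).standard_normal((1, 5, 4)), (2, 1, 1))
        tc_a = AxisTimecourse(wins, axes, np.ones((2, 5)), np.ones((2, 5)), "face",
                              np.arange(3), np.arange(3, 5))
        tc_b = AxisTimecourse(wins, -axes, np.ones((2, 5)), np.ones((2, 5)), "object",
                              np.arange(3), np.arange(3, 5))
        sims = similarity_matrices(tc_a, tc_b)
        assert np.allclose(sims[("face", "object")].values, -1.0)

    def test_grid_mismatch_rejected(self, tc_pair, switching_pop, features):
        tc_f, _ = tc_pair
        other = sliding_axes(
            switching_pop, features, "object", make_windows(0.0, 100.0), split_seed=2
        )
        with pytest.raises(ValueError):
            similarity_matrices(tc_f, other)


class TestAlignment:
    def test_stationary_object_rows_near_one(self, noswitch_pop, features, tc_pair):
        from axisdyn.axis_model import fit_axes_population, train_test_split_ids

        obj_idx = np.flatnonzero(noswitch_pop.mask("object"))
        tr, te = train_test_split_ids(len(obj_idx), seed=2)
        R = noswitch_pop.window_mean((50.0, 220.0))[:, obj_idx]
        W, *_ = fit_axes_population(R, features[obj_idx], tr, te)
        tc = sliding_axes(
            noswitch_pop, features, "object", make_windows(80.0, 220.0), split_seed=2
        )
        align = alignment_to_overall_object_axis(tc, W)
        assert np.nanmedian(align) > 0.98

    def test_switching_face_rows_change_sign(self, tc_pair, switching_pop, features):
        from axisdyn.axis_model import fit_axes_population, train_test_split_ids

        tc_f, _ = tc_pair
        obj_idx = np.flatnonzero(switching_pop.mask("object"))
        tr, te = train_test_split_ids(len(obj_idx), seed=2)
        R = switching_pop.window_mean((50.0, 220.0))[:, obj_idx]
        W, *_ = fit_axes_population(R, features[obj_idx], tr, te)
        align = alignment_to_overall_object_axis(tc_f, W)
        wins = tc_f.windows[:, 0]
        assert np.median(align[:, wins == 80]) > 0
        assert np.median(align[:, wins == 120]) < 0
        # divergence time lands at the switch
        div = divergence_times(tc_f, W)
        assert np.nanmedian(div) == pytest.approx(100.0, abs=20.0)

    def test_zero_norm_axis_gives_nan(self, tc_pair):
        tc_f, _ = tc_pair
        zeros = np.zeros((tc_f.n_cells, tc_f.axes.shape[2]))
        align = alignment_to_overall_object_axis(tc_f, zeros)
        assert np.all(np.isnan(align))


class TestDetectFlip:
    def test_switching_population_flips_at_switch_time(self, tc_pair):
        tc_f, _ = tc_pair
        rep = detect_flip(tc_f)
        assert rep.flip_fraction >= 0.9
        flagged = rep.flip_time_ms[rep.flip_flag]
        assert np.all(np.abs(flagged - 100.0) <= 20.0)

    def test_no_switch_control_below_false_positive_bound(self, noswitch_pop, features):
        tc = sliding_axes(
            noswitch_pop, features, "face", make_windows(0.0, 300.0), split_seed=1
        )
        rep = detect_flip(tc)
        assert rep.flip_fraction <= 0.05

    def test_antiparallel_axes_have_180_degree_angle(self, tc_pair):
        tc_f, _ = tc_pair
        wins = tc_f.windows
        axes = np.tile(np.array([1.0, 0.5, 0.0, 0.0]), (len(wins), 3, 1))
        li = 6  # [120, 140)
        axes[li:, :, :2] *= -1
        tc = AxisTimecourse(wins, axes, np.ones(axes.shape[:2]), np.ones(axes.shape[:2]),
                            "face", np.arange(3), np.arange(3, 5))
        rep = detect_flip(tc)
        assert np.allclose(rep.angle_deg, 180.0)
        assert rep.flip_fraction == 1.0
        assert np.all(rep.flip_time_ms == 120.0)

    def test_needs_two_feature_dims(self, tc_pair):
        tc_f, _ = tc_pair
        thin = AxisTimecourse(
            tc_f.windows, tc_f.axes[:, :, :1], tc_f.r2_train, tc_f.r2_test,
            "face", tc_f.train_ids, tc_f.test_ids,
        )
        with pytest.raises(ValueError):
            detect_flip(thin)


class TestAdaptiveShortWindow:
    def test_step_response_detected_near_onset(self):
        t = np.arange(-50.0, 300.0)
        rate = np.where(t >= 72, 10.0, 0.0)
        win = adaptive_short_window(rate, t)
        assert win is not None and 60 <= win[0] <= 80

    def test_flat_cell_returns_missing(self):
        t = np.arange(-50.0, 300.0)
        assert adaptive_short_window(np.ones_like(t), t) is None

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(3)
        t = np.arange(-50.0, 300.0)
        hits = 0
        for _ in range(200):
            rate = 5.0 + rng.standard_normal(len(t))
            if adaptive_short_window(rate, t) is not None:
                hits += 1
        # threshold is 2 s.d. of single-bin noise; 20-bin means rarely cross it
        assert hits / 200 <= 0.05

    def test_silent_baseline_uses_sd_floor(self):
        t = np.arange(-50.0, 300.0)
        rate = np.where(t >= 100, 0.25, 0.0)  # tiny response, silent baseline
        win = adaptive_short_window(rate, t)
        assert win == (100.0, 120.0)


class TestLatencySplitControl:
    def test_stationary_cell_all_axes_agree(self, noswitch_pop, features):
        f_idx = np.flatnonzero(noswitch_pop.mask("face"))
        re = noswitch_pop.window_mean((80.0, 100.0))[0, f_idx]
        rl = noswitch_pop.window_mean((120.0, 140.0))[0, f_idx]
        M = latency_split_control(re, rl, features[f_idx])
        assert M.to_numpy().min() > 0.95

    def test_switching_cell_most_effective_axes_anticorrelated(
        self, switching_pop, features
    ):
        f_idx = np.flatnonzero(switching_pop.mask("face"))
        vals = []
        for c in range(5):
            re = switching_pop.window_mean((80.0, 100.0))[c, f_idx]
            rl = switching_pop.window_mean((120.0, 140.0))[c, f_idx]
            M = latency_split_control(re, rl, features[f_idx])
            vals.append(M.loc["most_early", "most_late"])
        assert np.median(vals) < 0

    def test_delayed_weak_artifact_stays_correlated(
        self, stimset, space, features, noswitch_truth
    ):
        pop = simulate_artifact_population(
            "delayed_weak", stimset, noswitch_truth, n_repeats=1, space=space
        )
        f_idx = np.flatnonzero(pop.mask("face"))
        vals = []
        for c in range(5):
            re = pop.window_mean((80.0, 100.0))[c, f_idx]
            rl = pop.window_mean((120.0, 140.0))[c, f_idx]
            M = latency_split_control(re, rl, features[f_idx])
            vals.append(M.loc["most_early", "most_late"])
        assert np.median(vals) > 0

    def test_too_few_faces_rejected(self, features):
        with pytest.raises(ValueError):
            latency_split_control(np.ones(4), np.ones(4), features[:4])
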