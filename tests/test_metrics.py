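"""Population statistics: d', FSI, responsiveness, sparseness, PSI, dims, scores."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from axisdyn.metrics import (
    axis_change_score,
    dims_comparison,
    dims_for_variance,
    dprime_timecourse,
    face_selectivity_index,
    peak_dprime,
    psi,
    response_pc_pseudo_units,
    responsiveness_test,
    sparseness,
    sparseness_timecourse,
)
from axisdyn.simulate import ResponseTensor


def _cell(face_rates, obj_rates, T=300):
    """stimuli x T matrix with constant-in-time per-stimulus rates."""
    r = np.concatenate([face_rates, obj_rates]).astype(float)
    return np.tile(r[:, None], (1, T)), np.array(
        ["face"] * len(face_rates) + ["object"] * len(obj_rates)
    )


class TestDprime:
    def test_equal_categories_give_zero(self):
        R, cat = _cell([5, 5, 7, 7], [5, 5, 7, 7])
        assert np.allclose(dprime_timecourse(R, cat), 0.0)

    def test_hand_value(self):
        # face mean 10, object mean 6, both variances 4 -> d' = 2
        R, cat = _cell([8, 12, 10, 10], [4, 8, 6, 6])
        d = dprime_timecourse(R, cat)
        vf = np.var([8, 12, 10, 10], ddof=1)
        expect = (10 - 6) / np.sqrt(0.5 * (vf + vf))
        assert np.allclose(d, expect)

    def test_antisymmetric_under_label_swap(self, rng):
        R = rng.gamma(2.0, 3.0, size=(20, 50))
        cat = np.array(["face"] * 10 + ["object"] * 10)
        swapped = np.where(cat == "face", "object", "face")
        assert np.array_equal(
            dprime_timecourse(R, cat), -dprime_timecourse(R, swapped)
        )

    def test_zero_variance_conventions(self):
        R, cat = _cell([10, 10], [6, 6])
        assert np.all(dprime_timecourse(R, cat) == 10.0)  # clipped infinity
        R2, cat2 = _cell([6, 6], [6, 6])
        assert np.all(dprime_timecourse(R2, cat2) == 0.0)

    def test_peak_of_flat_timecourse_is_itself(self):
        t = np.arange(-50.0, 300.0)
        assert peak_dprime(np.full(len(t), 0.7), t) == pytest.approx(0.7)

    def test_peak_uses_80_to_140_interval(self):
        t = np.arange(-50.0, 300.0)
        d = np.zeros(len(t))
        d[(t >= 0) & (t < 40)] = 5.0  # early bump outside the peak interval
        d[(t >= 100) & (t < 120)] = 1.0
        assert peak_dprime(d, t) == pytest.approx(1.0)

    def test_single_stimulus_category_rejected(self):
        R, cat = _cell([5], [5, 6])
        with pytest.raises(ValueError):
            dprime_timecourse(R, cat)


class TestResponsiveness:
    def test_identical_windows_give_p_one(self):
        t = np.arange(-50.0, 300.0)
        R = np.ones((10, len(t))) * 4.0
        assert responsiveness_test(R, t) == 1.0

    def test_strong_step_response_highly_significant(self, rng):
        t = np.arange(-50.0, 300.0)
        R = rng.normal(5.0, 1.0, size=(100, len(t)))
        R[:, t >= 50] += 10.0
        assert responsiveness_test(R, t) < 1e-6

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        t = np.arange(-50.0, 300.0)
        rej = 0
        n = 300
        for _ in range(n):
            R = rng.normal(5.0, 1.0, size=(30, len(t)))
            if responsiveness_test(R, t) < 0.05 :
                rej += 1
        assert 0.02 < rej / n < 0.09


def test_fsi_contrast():
    R, cat = _cell([30, 30], [10, 10])
    t = np.arange(-50.0, 250.0)
    assert face_selectivity_index(R[:, : len(t)], cat, t) == pytest.approx(0.5)


class TestSparseness:
    def test_uniform_vector_is_zero(self):
        assert sparseness(np.full(8, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_is_one_minus_inverse_n(self):
        v = np.zeros(4)
        v[2] = 9.0
        assert sparseness(v) == pytest.approx(0.75)

    def test_hand_value(self):
        assert sparseness(np.array([3.0, 1.0])) == pytest.approx(0.2)

    def test_all_zero_is_missing(self):
        assert np.isnan(sparseness(np.zeros(5)))

    def test_timecourse_category_means(self):
        rates = np.zeros((4, 3, 100))
        rates[:, 0, :] = 1.0  # uniform -> S = 0
        rates[0, 1, :] = 1.0  # one-hot -> S = 0.75
        rates[:, 2, :] = 1.0
        pop = ResponseTensor(
            rates=rates,
            time_ms=np.arange(0.0, 100.0),
            n_repeats=1,
            category=np.array(["face", "face", "object"]),
        )
        S, means = sparseness_timecourse(pop)
        assert np.allclose(S[0], 0.0, atol=1e-12)
        assert np.allclose(S[1], 0.75)
        assert np.allclose(means["face"], 0.375)
        assert np.allclose(means["object"], 0.0, atol=1e-12)


class TestPSI:
    def test_identical_group_means_give_zero(self):
        R = np.tile(np.array([[1.0], [2.0]]), (1, 4))
        R += np.array([0.1, 0.1, -0.1, -0.1])  # within-group variation only
        assert psi(R, np.array([0, 1, 0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_scale_and_translation_invariance(self, rng):
        R = rng.gamma(3.0, 2.0, size=(12, 30))
        g = rng.integers(0, 3, size=30)
        base = psi(R, g)
        assert psi(R * 4.2, g) == pytest.approx(base, abs=1e-12)
        assert psi(R + 11.0, g) == pytest.approx(base, abs=1e-12)

    def test_matches_hand_geometry_oracle(self):
        R = np.eye(3)  # three orthogonal unit population vectors
        got = psi(R, np.arange(3))
        expect = pdist(np.eye(3)).mean() / np.eye(3).std()
        assert got == pytest.approx(expect, abs=1e-12)
        assert pdist(np.eye(3)).mean() == pytest.approx(np.sqrt(2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            psi(np.ones((3, 4)), np.zeros(4, dtype=int))  # zero pooled s.d.
        with pytest.raises(ValueError):
            psi(np.random.rand(3, 4), np.zeros(4, dtype=int))  # one group


class TestDimsForVariance:
    def test_rank_one_matrix_needs_one_dim(self, rng):
        M = np.outer(rng.standard_normal(20), rng.standard_normal(100))
        assert dims_for_variance(M, 0.9) == 1

    def test_isotropic_matrix_needs_about_q_times_rank(self, rng):
        M = rng.standard_normal((40, 4000))
        m = dims_for_variance(M, 0.9)
        assert 30 <= m <= 39

    def test_richer_late_window_needs_more_dims(self, rng):
        n_stim = 150
        early = rng.standard_normal((60, 3)) @ rng.standard_normal((3, n_stim))
        late = rng.standard_normal((60, 30)) @ rng.standard_normal((30, n_stim))
        early += 0.01 * rng.standard_normal(early.shape)
        late += 0.01 * rng.standard_normal(late.shape)
        res = dims_comparison(early, late, n_boot=50, seed=1)
        assert res["m_late"] > res["m_early"]
        assert res["frac_late_gt_early"] >= 0.95


class TestResponsePCPseudoUnits:
    def test_identical_cells_make_pc2_degenerate(self, stimset, space, features):
        import axisdyn as ad

        truth = ad.make_switching_truth(12, 2, seed=40)
        truth.early_axes[1] = truth.early_axes[0]
        truth.late_face_axes[1] = truth.late_face_axes[0]
        truth.object_axes[1] = truth.object_axes[0]
        truth.gain[:] = 5.0
        truth.baseline_hz[:] = 10.0
        truth.latency_ms[:] = 55.0
        pop = ad.simulate_population(stimset, truth, n_repeats=1, space=space)
        out = response_pc_pseudo_units(pop, features, k_extremes=3)
        assert out["degenerate"][1]
        assert not out["degenerate"][0]

    def test_extreme_sets_partition_when_k_is_category_size(
        self, switching_pop, features
    ):
        n_face = int(switching_pop.mask("face").sum())
        out = response_pc_pseudo_units(switching_pop, features, k_extremes=n_face)
        entry = out["per_pc"][0]["face"]
        top = set(entry["top_ids"][0])
        assert len(top) == n_face

    def test_switching_population_changes_preferred_stimuli(
        self, switching_pop, features
    ):
        from axisdyn.dynamics import make_windows

        out = response_pc_pseudo_units(
            switching_pop, features, k_extremes=10,
            windows=make_windows(80.0, 140.0),
        )
        entry = out["per_pc"][0]["face"]
        pre = set(entry["top_ids"][0])  # [80, 100)
        post = set(entry["top_ids"][-1])  # [120, 140)
        assert len(pre & post) < 10


class TestAxisChangeScore:
    def test_direction_contract(self, switching_pop):
        acs = axis_change_score(switching_pop, seed=0)
        assert acs.coef < 0  # low correlation -> face-side score
        f = switching_pop.mask("face")
        assert np.nanmedian(acs.score[f]) > np.nanmedian(acs.score[~f])

    def test_invariant_to_cell_and_stimulus_order(self, switching_pop):
        import copy

        acs = axis_change_score(switching_pop, seed=0)
        rng = np.random.default_rng(1)
        perm_cells = rng.permutation(switching_pop.n_cells)
        pop2 = copy.copy(switching_pop)
        pop2 = ResponseTensor(
            rates=switching_pop.rates[perm_cells],
            time_ms=switching_pop.time_ms,
            n_repeats=switching_pop.n_repeats,
            category=switching_pop.category,
            ids=switching_pop.ids,
        )
        acs2 = axis_change_score(pop2, seed=0)
        assert np.allclose(acs.early_late_corr, acs2.early_late_corr, atol=1e-10)

    def test_too_few_cells_rejected(self, switching_pop):
        pop = ResponseTensor(
            rates=switching_pop.rates[:2],
            time_ms=switching_pop.time_ms,
            n_repeats=1,
            category=switching_pop.category,
        )
        with pytest.raises(ValueError):
            axis_change_score(pop, exclude_percentiles=(0.0, 100.0))
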