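"""Bias-compensated STA: estimator identities, significance, convergence."""

import numpy as np
import pandas as pd
import pytest

import fgfield as fg
from fgfield.sta import _conv_model, fit_convergence


def _table_from_totals(labels, totals):
    rows = [(sid, 0, 0, float(t)) for sid, t in zip(labels.ids, totals)]
    return fg.SpikeTable(pd.DataFrame(rows, columns=["stimulus_id", "trial", "pre_count", "stim_count"]))


class TestComputeSTA:
    def test_flat_null_is_exactly_zero(self, halfplane_set):
        tab = _table_from_totals(halfplane_set, np.full(halfplane_set.N, 7))
        sta = fg.compute_sta(halfplane_set, tab)
        assert np.abs(sta.grid).max() == 0.0

    def test_single_support_gives_label_minus_mean(self, curved_set):
        totals = np.zeros(curved_set.N)
        totals[3] = 5
        sta = fg.compute_sta(curved_set, _table_from_totals(curved_set, totals))
        expected = curved_set.labels[3].grid - fg.ensemble_mean_label(curved_set)
        np.testing.assert_allclose(sta.grid, expected, atol=1e-12)

    @pytest.mark.parametrize("scale", [2.0, 7.5])
    def test_scale_invariance(self, halfplane_set, scale):
        rng = np.random.default_rng(0)
        totals = rng.poisson(5.0, halfplane_set.N).astype(float) + 1
        a = fg.compute_sta(halfplane_set, _table_from_totals(halfplane_set, totals))
        b = fg.compute_sta(halfplane_set, _table_from_totals(halfplane_set, totals * scale))
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-12)

    def test_values_bounded_by_unit_interval(self, halfplane_set):
        rng = np.random.default_rng(1)
        totals = rng.poisson(3.0, halfplane_set.N).astype(float)
        totals[0] += 1
        sta = fg.compute_sta(halfplane_set, _table_from_totals(halfplane_set, totals))
        assert np.abs(sta.grid).max() <= 1.0 + 1e-12

    def test_all_zero_spikes_rejected(self, halfplane_set):
        with pytest.raises(ValueError):
            fg.compute_sta(halfplane_set, _table_from_totals(halfplane_set, np.zeros(halfplane_set.N)))

    def test_dot_identifiability_noiseless(self, dot_set_9):
        k = fg.make_dog_kernel((4, 4), 0.9, 1.5, 2.5, 9)
        neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=k, gain=20, noise="exact")
        tab = fg.simulate_responses(neuron, dot_set_9, 1, seed=0)
        sta = fg.compute_sta(dot_set_9, tab)
        assert fg.cosine_similarity(k, sta) == pytest.approx(1.0, abs=1e-10)


class TestPermutationTest:
    def test_add_one_estimator_with_single_perm(self, halfplane_set):
        rng = np.random.default_rng(5)
        totals = rng.poisson(4.0, halfplane_set.N).astype(float) + 1
        tab = _table_from_totals(halfplane_set, totals)
        p = fg.permutation_test(halfplane_set, tab, n_perm=1, seed=0)
        assert p in (0.5, 1.0)

    def test_degenerate_equal_counts_p_one(self, halfplane_set):
        tab = _table_from_totals(halfplane_set, np.full(halfplane_set.N, 3))
        assert fg.permutation_test(halfplane_set, tab, n_perm=50, seed=0) == 1.0

    def test_ideal_cell_significant(self, halfplane_set, crf_left):
        cc = crf_left.center_cell(25)
        neuron = fg.VirtualNeuron(kind="ideal_fg", preference="figure", crf_center=cc)
        tab = fg.simulate_responses(neuron, halfplane_set, 10, seed=0)
        assert fg.permutation_test(halfplane_set, tab, n_perm=200, seed=1) < 0.05


@pytest.fixture(scope="module")
def noisy_cell(halfplane_set):
    k = fg.make_dog_kernel((12, 8), 0.4, 2.0, 3.0, 25)
    neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=k, gain=30, noise="poisson")
    return fg.simulate_responses(neuron, halfplane_set, 10, seed=3)


class TestConvergence:

    def test_full_size_equals_full_magnitude(self, halfplane_set, noisy_cell):
        sizes, curve = fg.convergence_curve(halfplane_set, noisy_cell, step=10, reps=3, seed=0)
        assert sizes[-1] == halfplane_set.N
        full = fg.compute_sta(halfplane_set, noisy_cell).magnitude
        assert curve[-1] == pytest.approx(full, rel=1e-12)

    def test_deterministic_under_seed(self, halfplane_set, noisy_cell):
        a = fg.convergence_curve(halfplane_set, noisy_cell, step=10, reps=5, seed=8)
        b = fg.convergence_curve(halfplane_set, noisy_cell, step=10, reps=5, seed=8)
        np.testing.assert_array_equal(a[1], b[1])

    def test_null_cell_curve_decays(self, halfplane_set):
        neuron = fg.VirtualNeuron(kind="non_fg", constant_rate=5, noise="poisson")
        tab = fg.simulate_responses(neuron, halfplane_set, 10, seed=2)
        sizes, curve = fg.convergence_curve(halfplane_set, tab, step=6, reps=20, seed=0)
        # sampling noise in the magnitude scales down with ensemble size
        assert curve[0] > curve[-1]


class TestFitConvergence:
    def test_flat_curve_saturated(self):
        sizes = np.arange(10, 90, 10, dtype=float)
        fit = fit_convergence(sizes, np.full(8, 5.0))
        assert fit.a == pytest.approx(5.0, rel=1e-6)
        assert fit.ratio == pytest.approx(1.0, abs=1e-6)
        assert fit.convergent

    def test_family_round_trip_recovers_asymptote(self):
        p_true = np.array([10.0, 0.8, 30.0, 1.2, 0.0, 1.0])
        x = np.arange(20, 221, 20, dtype=float)
        fit = fit_convergence(x, _conv_model(x, p_true))
        assert fit.a == pytest.approx(10.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_convergence(np.arange(5.0), np.arange(5.0) + 1)

    def test_ratio_threshold_gates_effectiveness(self, halfplane_set, crf_left):
        cc = crf_left.center_cell(25)
        neuron = fg.VirtualNeuron(kind="ideal_fg", preference="figure", crf_center=cc)
        tab = fg.simulate_responses(neuron, halfplane_set, 10, seed=0)
        sizes, curve = fg.convergence_curve(halfplane_set, tab, step=6, reps=20, seed=4)
        fit = fit_convergence(sizes, curve)
        kern = fg.compute_sta(halfplane_set, tab)
        kern.p_perm = fg.permutation_test(halfplane_set, tab, n_perm=200, seed=0)
        kern.convergence_ratio = fit.ratio
        assert kern.effective == (kern.p_perm < 0.05 and fit.ratio >= 0.9)
        assert kern.effective  # the ideal cell passes both screens


class TestIdealKernel:
    def test_matches_closed_form_angle_law(self, halfplane_dense, ideal_kernel):
        # uniform orientations: M(x) = 1 - 2*angle(x, p)/pi with p the
        # CRF-center direction from the patch center
        from fgfield.synthetic_data import grid_coords

        dx, dy = grid_coords(25)
        p = np.array([8 - 12, 12 - 12], dtype=float)  # (dx, dy) of CRF center
        dots = dx * p[0] + dy * p[1]
        norms = np.hypot(dx, dy) * np.hypot(*p)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(dots / norms, -1, 1))
        analytic = 1 - 2 * theta / np.pi
        mask = norms > 0
        assert np.abs(ideal_kernel.grid[mask] - analytic[mask]).max() < 0.06

    def test_antagonistic_structure(self, ideal_kernel):
        assert ideal_kernel.grid[12, 6] > 0.5   # CRF side
        assert ideal_kernel.grid[12, 18] < -0.5  # opposite side

    def test_figure_and_ground_kernels_are_negatives(self, halfplane_dense, crf_left):
        kf = fg.ideal_rffg(halfplane_dense, crf_left, "figure")
        kg = fg.ideal_rffg(halfplane_dense, crf_left, "ground")
        np.testing.assert_allclose(kf.grid, -kg.grid, atol=1e-12)

    def test_pr_ratio_near_half(self, ideal_kernel):
        assert fg.pr_ratio(ideal_kernel, "figure") == pytest.approx(0.5, abs=0.03)

    def test_preference_must_be_valid(self, halfplane_dense, crf_left):
        with pytest.raises(ValueError):
            fg.ideal_rffg(halfplane_dense, crf_left, "both")
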