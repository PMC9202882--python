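"""Generators: label ensembles, ground-truth kernels, response simulation."""

import numpy as np
import pytest

import fgfield as fg
from fgfield.synthetic_data import center_cell


def _boundary_through_center(label):
    """Center cell has a 4-neighbor of opposite sign."""
    G = label.grid_size
    r, c = center_cell(G)
    v = label.grid[r, c]
    neigh = [label.grid[r + dr, c + dc] for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    return any(n == -v for n in neigh)


class TestHalfplane:
    def test_axis_aligned_construction(self):
        s = fg.gen_halfplane_labels(2, 25)
        assert s.N == 4
        grids = {sid: s[sid].grid for sid in s.ids}
        # one orientation gives top/bottom halves, the other left/right
        kinds = set()
        for g in grids.values():
            col_const = (g == g[:, :1]).all()
            row_const = (g == g[:1, :]).all()
            kinds.add("rows" if col_const else "cols" if row_const else "other")
        assert kinds == {"rows", "cols"}

    def test_count_matches_full_scale_design(self):
        assert fg.gen_halfplane_labels(105, 25).N == 210

    def test_mirror_partner_is_sign_swap(self, halfplane_set):
        for lab in halfplane_set:
            partner = halfplane_set[lab.mirror_partner]
            np.testing.assert_array_equal(partner.grid, -lab.grid)

    def test_boundary_through_center_everywhere(self, halfplane_set):
        assert all(_boundary_through_center(lab) for lab in halfplane_set)

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            fg.gen_halfplane_labels(1, 25)


class TestCurved:
    def test_deterministic_under_seed(self):
        a = fg.gen_curved_labels(10, 25, 1.5, seed=3)
        b = fg.gen_curved_labels(10, 25, 1.5, seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.grid, sb.grid)

    def test_zero_curvature_gives_straight_boundaries(self):
        s = fg.gen_curved_labels(6, 25, 0.0, seed=5)
        # a straight boundary through the center makes the label equal to
        # minus its point reflection except on the boundary line itself
        for lab in s:
            g = lab.grid
            mismatch = np.sum(g[::-1, ::-1] != -g)
            assert mismatch <= 25

    def test_boundary_through_center_and_both_sides(self):
        s = fg.gen_curved_labels(105, 25, 2.0, seed=7)
        assert s.N == 210
        assert all(_boundary_through_center(lab) for lab in s)

    def test_swap_closure_zero_mean(self, curved_set):
        assert np.abs(fg.ensemble_mean_label(curved_set)).max() == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            fg.gen_curved_labels(0, 25)
        with pytest.raises(ValueError):
            fg.gen_curved_labels(5, 25, curvature_sd=-1.0)


class TestDots:
    def test_exhaustive_count(self):
        assert fg.gen_dot_stimuli(25).N == 1250
        assert fg.gen_dot_stimuli(2).N == 8

    def test_zero_mean_by_pairing(self, dot_set_9):
        assert np.abs(fg.ensemble_mean_label(dot_set_9)).max() == 0.0

    def test_each_dot_is_a_single_cell(self, dot_set_9):
        for lab in dot_set_9:
            assert np.abs(lab.grid).sum() == 1


class TestTranslated:
    def test_zero_shift_is_identity(self, halfplane_set):
        out = fg.gen_translated_labels(halfplane_set, [(0, 0)])
        for a, b in zip(halfplane_set, out):
            np.testing.assert_array_equal(a.grid, b.grid)

    def test_halfplane_boundary_offset(self):
        s = fg.gen_halfplane_labels(2, 25)
        vert = next(lab for lab in s if (lab.grid == lab.grid[:1, :]).all()
                    and lab.grid[0, 0] != lab.grid[0, -1])
        out = fg.gen_translated_labels(fg.StimulusSet([vert]), [(2, 0)])
        shifted = out.labels[0].grid
        np.testing.assert_array_equal(shifted[:, 2:], vert.grid[:, :-2])
        # vacated columns take the nearer (edge) side's value
        np.testing.assert_array_equal(shifted[:, 0], vert.grid[:, 0])

    def test_magnitude_spectra_close_between_sets(self, halfplane_set):
        out = fg.gen_translated_labels(halfplane_set, [(2, 1)])

        def spec(s):
            m = np.mean(
                [np.abs(np.fft.fft2(lab.grid.astype(float))) for lab in s], axis=0
            )
            m[0, 0] = 0.0  # edge fill shifts the area balance (DC term) only
            return m

        a, b = spec(halfplane_set), spec(out)
        assert np.linalg.norm(a - b) / np.linalg.norm(a) < 0.1

    def test_excessive_shift_rejected(self, halfplane_set):
        with pytest.raises(ValueError):
            fg.gen_translated_labels(halfplane_set, [(25, 0)])


class TestDoGKernel:
    def test_odd_symmetry_about_integer_center(self):
        k = fg.make_dog_kernel((12, 12), 0.7, 2.0, 3.0, 25)
        np.testing.assert_allclose(k[::-1, ::-1], -k, atol=1e-12)

    def test_unit_norm(self):
        k = fg.make_dog_kernel((10, 14), 1.2, 1.5, 4.0, 25)
        assert np.linalg.norm(k) == pytest.approx(1.0)

    def test_positive_projection_on_aligned_halfplane(self):
        # positive lobe points along +x for orientation 0: the label with
        # figure on the right projects positively
        k = fg.make_dog_kernel((12, 12), 0.0, 2.0, 3.0, 25)
        dx = np.arange(25) - 12
        label = np.where(dx[None, :] > 0, 1, -1)
        assert np.sum(k * label) > 0

    def test_bad_sigmas_rejected(self):
        with pytest.raises(ValueError):
            fg.make_dog_kernel((12, 12), 0.0, -1.0, 2.0, 25)


class TestSimulation:
    def test_ideal_fg_contract(self, halfplane_set, crf_left):
        cc = crf_left.center_cell(25)
        neuron = fg.VirtualNeuron(kind="ideal_fg", preference="figure", crf_center=cc)
        tab = fg.simulate_responses(neuron, halfplane_set, 3, seed=0)
        for lab in halfplane_set:
            counts = tab.frame.query(f"stimulus_id == '{lab.stimulus_id}'")["stim_count"]
            expect = 1 if lab.grid[cc] == 1 else 0
            assert (counts == expect).all()

    def test_non_fg_constant(self, halfplane_set):
        tab = fg.simulate_responses(
            fg.VirtualNeuron(kind="non_fg", constant_rate=4), halfplane_set, 2, seed=0
        )
        assert (tab.frame["stim_count"] == 4).all()

    def test_rectification_zeroes_negative_drive(self, halfplane_set):
        lab0 = halfplane_set.labels[0]
        k = -lab0.grid.astype(float)  # anti-aligned with lab0
        neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=k, gain=1.0, noise="exact")
        tab = fg.simulate_responses(neuron, halfplane_set, 1, seed=0)
        row = tab.frame.query(f"stimulus_id == '{lab0.stimulus_id}'")
        assert (row["stim_count"] == 0).all()

    def test_grid_mismatch_rejected(self, halfplane_set):
        neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=np.zeros((9, 9)))
        with pytest.raises(ValueError, match="kernel shape"):
            fg.simulate_responses(neuron, halfplane_set, 1, seed=0)

    def test_poisson_reproducible_under_seed(self, halfplane_set):
        neuron = fg.VirtualNeuron(kind="non_fg", constant_rate=5, noise="poisson",
                                  baseline_rate=1.0)
        a = fg.simulate_responses(neuron, halfplane_set, 3, seed=9)
        b = fg.simulate_responses(neuron, halfplane_set, 3, seed=9)
        assert a.frame.equals(b.frame)
        assert (a.frame["pre_count"] > 0).any()


class TestGratingMap:
    def test_peak_near_true_center(self, crf_left):
        cmap, pos = fg.gen_grating_response_map(crf_left, gain=30.0)
        peak = np.unravel_index(np.argmax(cmap), cmap.shape)
        d = np.hypot(pos[peak][0] - crf_left.center[0], pos[peak][1] - crf_left.center[1])
        dists = np.hypot(pos[..., 0] - crf_left.center[0], pos[..., 1] - crf_left.center[1])
        assert d == dists.min()

    def test_zero_gain_flat(self, crf_left):
        cmap, _ = fg.gen_grating_response_map(crf_left, gain=0.0)
        assert np.ptp(cmap) == 0.0
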