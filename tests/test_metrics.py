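"""Kernel geometry metrics and population alignment operators."""

import numpy as np
import pytest

import fgfield as fg
from fgfield.crf_estimation import CRF
from fgfield.metrics import AlignmentSpec, center_align, preferred_region


class TestCosine:
    def test_identity_and_negation(self, ideal_kernel):
        assert fg.cosine_similarity(ideal_kernel, ideal_kernel) == pytest.approx(1.0)
        neg = fg.RFFG(grid=-ideal_kernel.grid)
        assert fg.cosine_similarity(ideal_kernel, neg) == pytest.approx(-1.0)

    def test_orthogonal_halfplanes(self):
        s = fg.gen_halfplane_labels(2, 25)
        grids = [lab.grid.astype(float) for lab in s]
        vert = next(g for g in grids if (g == g[:1, :]).all())
        horiz = next(g for g in grids if (g == g[:, :1]).all())
        # remove the tie-broken boundary line before comparing
        v = vert - vert.mean()
        h = horiz - horiz.mean()
        assert abs(fg.cosine_similarity(v, h)) < 0.01

    def test_scale_invariance(self, ideal_kernel):
        assert fg.cosine_similarity(ideal_kernel.grid * 5.0, ideal_kernel) == pytest.approx(1.0)

    def test_zero_kernel_rejected(self, ideal_kernel):
        with pytest.raises(ValueError):
            fg.cosine_similarity(np.zeros((25, 25)), ideal_kernel)


class TestPRRatio:
    def test_all_positive_kernel(self):
        assert fg.pr_ratio(np.ones((5, 5)), "figure") == 1.0

    def test_antisymmetric_kernel_balanced(self):
        dx = np.arange(25) - 12.0
        k = np.tile(dx, (25, 1))
        assert fg.pr_ratio(k, "figure") == pytest.approx(0.5, abs=0.03)

    def test_scale_invariant(self, ideal_kernel):
        a = fg.pr_ratio(ideal_kernel, "figure")
        b = fg.pr_ratio(ideal_kernel.grid * 7.0, "figure")
        assert a == b

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError):
            fg.pr_ratio(np.zeros((5, 5)), "figure")


class TestOverlapRatio:
    def test_perfect_overlap(self):
        crf = CRF(center=(12.0, 12.0), sd_major=4.0, sd_minor=3.0,
                  orientation=0.3, amplitude=1.0)
        ellipse = crf.ellipse_mask(25)
        k = np.where(ellipse, 1.0, -1.0)
        assert fg.overlap_ratio(crf, k, "figure") == 1.0

    def test_disjoint_sets(self):
        crf = CRF(center=(5.0, 5.0), sd_major=2.0, sd_minor=2.0,
                  orientation=0.0, amplitude=1.0)
        k = -np.ones((25, 25))
        k[20:, 20:] = 1.0
        assert fg.overlap_ratio(crf, k, "figure") == 0.0

    def test_half_covered_ellipse_brute_force(self):
        crf = CRF(center=(12.0, 12.0), sd_major=3.0, sd_minor=3.0,
                  orientation=0.0, amplitude=1.0)
        dx = np.arange(25) - 12
        k = np.where(dx[None, :] <= 0, 1.0, -1.0) * np.ones((25, 1))
        got = fg.overlap_ratio(crf, k, "figure")
        # independent cell enumeration
        rows, cols = np.mgrid[0:25, 0:25].astype(float)
        inside = ((rows - 12) ** 2 + (cols - 12) ** 2) <= 9.0
        pref = k > 0
        expected = (inside & pref).sum() / (inside | pref).sum()
        assert got == pytest.approx(expected)


class TestRotateAlign:
    def test_already_aligned_kernel_barely_moves(self, ideal_kernel):
        # the figure CoG of this kernel already lies on the left axis up
        # to pixelation, so alignment is a near-identity
        out = fg.rotate_align(ideal_kernel, "figure")
        scale = np.abs(ideal_kernel.grid).max()
        assert np.abs(out.grid[4:21, 4:21] - ideal_kernel.grid[4:21, 4:21]).max() < 0.05 * scale

    def test_quarter_turn_copy_aligns_to_same(self, ideal_kernel):
        from fgfield.metrics import rotate_grid

        rotated = fg.RFFG(grid=rotate_grid(ideal_kernel.grid, np.pi / 2))
        a = fg.rotate_align(ideal_kernel, "figure").grid
        b = fg.rotate_align(rotated, "figure").grid
        scale = np.abs(a).max()
        # compare away from the border where rotation fills zeros
        assert np.abs(a[4:21, 4:21] - b[4:21, 4:21]).max() < 0.05 * scale

    def test_cog_lands_on_left_axis(self, ideal_kernel):
        from fgfield.metrics import _preferred_cog, rotate_grid

        # start from a copy whose CoG points up, then align
        tilted = fg.RFFG(grid=rotate_grid(ideal_kernel.grid, np.pi / 2))
        out = fg.rotate_align(tilted, "figure")
        r, c = _preferred_cog(out.grid, "figure", 0.05)
        angle = np.arctan2(r - 12, c - 12)
        assert abs(abs(angle) - np.pi) < 0.05  # pointing left

    def test_ground_preference_aligns_right(self, ideal_kernel):
        from fgfield.metrics import _preferred_cog

        neg = fg.RFFG(grid=-ideal_kernel.grid)  # ground-preferring copy
        out = fg.rotate_align(neg, "ground")
        r, c = _preferred_cog(out.grid, "ground", 0.05)
        assert abs(np.arctan2(r - 12, c - 12)) < 0.05  # pointing right

    def test_centered_cog_rejected(self):
        k = np.ones((25, 25))
        with pytest.raises(ValueError, match="rotation undefined"):
            fg.rotate_align(k, "figure")

    def test_inverse_rotation_round_trip_on_smooth_kernel(self):
        from fgfield.metrics import rotate_grid

        k = fg.make_dog_kernel((12, 12), 0.5, 2.0, 3.0, 25)
        scale = np.abs(k).max()
        for theta in (0.4, 1.1, np.pi / 2):
            back = rotate_grid(rotate_grid(k, theta), -theta)
            err = np.abs(back[4:21, 4:21] - k[4:21, 4:21]).max()
            assert err < 0.02 * scale, theta


class TestScaleByCRF:
    def test_identity_when_already_at_target(self, ideal_kernel, crf_left):
        out = fg.scale_by_crf(ideal_kernel, crf_left, target_sd=crf_left.mean_sd)
        np.testing.assert_allclose(out.grid, ideal_kernel.grid, atol=1e-9)

    def test_double_then_halve_round_trip(self, ideal_kernel, crf_left):
        up = fg.scale_by_crf(ideal_kernel, crf_left, target_sd=crf_left.mean_sd * 2)
        crf2 = CRF(center=crf_left.center, sd_major=crf_left.sd_major * 2,
                   sd_minor=crf_left.sd_minor * 2, orientation=0.0, amplitude=1.0)
        down = fg.scale_by_crf(up, crf2, target_sd=crf_left.mean_sd)
        scale = np.abs(ideal_kernel.grid).max()
        # interior cells survive the magnify/shrink cycle
        assert np.abs(down.grid[8:17, 4:13] - ideal_kernel.grid[8:17, 4:13]).max() < 0.02 * scale

    def test_degenerate_target_rejected(self, ideal_kernel, crf_left):
        with pytest.raises(ValueError):
            fg.scale_by_crf(ideal_kernel, crf_left, target_sd=0.0)


class TestPopulationMean:
    def test_identical_kernels_average_to_normalized_self(self, ideal_kernel):
        crf_center = CRF(center=(12.0, 12.0), sd_major=3.0, sd_minor=3.0,
                         orientation=0.0, amplitude=1.0)
        spec = AlignmentSpec(mode="crf_centered")
        out = fg.population_mean([ideal_kernel, ideal_kernel], spec,
                                 crfs=[crf_center, crf_center])
        expected = ideal_kernel.grid / np.abs(ideal_kernel.grid).max()
        np.testing.assert_allclose(out.grid, expected, atol=1e-9)

    def test_kernel_plus_negation_cancels(self, ideal_kernel):
        crf_center = CRF(center=(12.0, 12.0), sd_major=3.0, sd_minor=3.0,
                         orientation=0.0, amplitude=1.0)
        spec = AlignmentSpec(mode="crf_centered")
        out = fg.population_mean(
            [ideal_kernel, fg.RFFG(grid=-ideal_kernel.grid)], spec,
            crfs=[crf_center, crf_center],
        )
        assert np.abs(out.grid).max() < 1e-12

    def test_ideal_population_has_central_preferred_lobe(self, halfplane_dense):
        # figure-preferring ideal cells at scattered CRF centers, translated
        # into register: the mean shows a positive lobe at the patch center
        rng = np.random.default_rng(0)
        kernels, crfs = [], []
        for _ in range(6):
            center = (float(rng.uniform(8, 16)), float(rng.uniform(8, 16)))
            crf = CRF(center=center, sd_major=3.0, sd_minor=3.0,
                      orientation=0.0, amplitude=1.0)
            kernels.append(fg.ideal_rffg(halfplane_dense, crf, "figure"))
            crfs.append(crf)
        out = fg.population_mean(kernels, AlignmentSpec(mode="crf_centered"), crfs=crfs)
        assert out.grid[12, 12] > 0.5
        assert out.grid[12, 12] == np.max(out.grid[10:15, 10:15])

    def test_zero_kernel_excluded_with_warning(self, ideal_kernel):
        crf_center = CRF(center=(12.0, 12.0), sd_major=3.0, sd_minor=3.0,
                         orientation=0.0, amplitude=1.0)
        with pytest.warns(UserWarning, match="excluded"):
            out = fg.population_mean(
                [ideal_kernel, fg.RFFG(grid=np.zeros((25, 25)))],
                AlignmentSpec(mode="crf_centered"),
                crfs=[crf_center, crf_center],
            )
        expected = ideal_kernel.grid / np.abs(ideal_kernel.grid).max()
        np.testing.assert_allclose(out.grid, expected, atol=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            fg.population_mean([], AlignmentSpec())


def test_preferred_region_respects_threshold():
    k = np.zeros((9, 9))
    k[0, 0] = 1.0
    k[8, 8] = 0.01  # below 5% of max
    k[4, 4] = -0.5
    region = preferred_region(k, "figure", eps=0.05)
    assert region[0, 0] and not region[8, 8] and not region[4, 4]
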