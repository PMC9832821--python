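"""Heatmaps, spherical smoothing, voxel/region statistics, SAV maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from q3d import (EffectRegionSpec, MetricHeatmap, PhantomSpec, CohortSpec,
                 SmoothingKernel, adjust_bh, aggregate_to_voxels, binarize_sav,
                 generate_cohort, make_toy_atlas, region_stats,
                 smooth_spherical, voxelwise_ttest)

GRID = (40, 40, 30)


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Hand-rolled BH: p_adj(i) = min_{j>=i} min(1, m p_(j) / j)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def plaques_at(points_um, volumes=None, maturities=None):
    pts = np.atleast_2d(points_um).astype(float)
    n = len(pts)
    return pd.DataFrame({
        "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
        "volume_um3": volumes if volumes is not None else np.full(n, 500.0),
        "maturity": maturities if maturities is not None else np.full(n, 0.5),
    })


class TestAggregate:
    def test_empty_table(self):
        maps = aggregate_to_voxels(plaques_at(np.empty((0, 3))), GRID)
        assert maps["count"].grid.sum() == 0
        assert np.isnan(maps["mean_size"].grid).all()

    def test_three_plaques_one_voxel(self):
        pts = np.array([[110.0, 110.0, 110.0]] * 3)
        maps = aggregate_to_voxels(plaques_at(pts, volumes=[100, 200, 300]), GRID)
        assert maps["count"].grid[4, 4, 4] == 3
        assert maps["mean_size"].grid[4, 4, 4] == pytest.approx(200.0)
        assert maps["count"].grid.sum() == 3

    def test_random_plaques_match_histogram_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.random((10000, 3)) * np.array(GRID) * 25.0
        maps = aggregate_to_voxels(plaques_at(pts), GRID)
        oracle, _ = np.histogramdd(pts, bins=GRID,
                                   range=[(0, s * 25.0) for s in GRID])
        np.testing.assert_array_equal(maps["count"].grid, oracle)

    def test_undefined_maturity_excluded_from_mean_only(self):
        pts = np.array([[10.0, 10.0, 10.0]] * 2)
        df = plaques_at(pts, maturities=[0.8, np.nan])
        maps = aggregate_to_voxels(df, GRID)
        assert maps["count"].grid[0, 0, 0] == 2
        assert maps["mean_maturity"].grid[0, 0, 0] == pytest.approx(0.8)


class TestKernel:
    def test_size_matches_brute_force_enumeration(self):
        kernel = SmoothingKernel(15)
        count = sum(
            1
            for x in range(-7, 8) for y in range(-7, 8) for z in range(-7, 8)
            if x * x + y * y + z * z <= 7.5 ** 2
        )
        assert kernel.size == count == 1791

    def test_reflection_symmetry(self):
        foot = SmoothingKernel(15).footprint
        for ax in range(3):
            np.testing.assert_array_equal(foot, np.flip(foot, axis=ax))


class TestSmoothing:
    def test_single_interior_plaque_paints_kernel_sphere(self):
        kernel = SmoothingKernel(15)
        maps = aggregate_to_voxels(plaques_at([[500.0, 500.0, 375.0]]), GRID)
        sm = smooth_spherical(maps["count"], kernel)
        assert sm.grid.sum() == pytest.approx(kernel.size, rel=1e-9)
        center = tuple(np.argwhere(maps["count"].grid == 1)[0])
        assert sm.grid[center] == pytest.approx(1.0)

    def test_two_distant_plaques_disjoint_support(self):
        kernel = SmoothingKernel(15)
        pts = [[200.0, 200.0, 200.0], [800.0, 800.0, 500.0]]
        maps = aggregate_to_voxels(plaques_at(pts), GRID)
        sm = smooth_spherical(maps["count"], kernel)
        assert sm.grid.sum() == pytest.approx(2 * kernel.size, rel=1e-9)

    def test_empty_map_stays_empty(self):
        maps = aggregate_to_voxels(plaques_at(np.empty((0, 3))), GRID)
        assert smooth_spherical(maps["count"]).grid.sum() == 0

    def test_interior_mass_identity(self):
        """sum(smoothed) = |kernel| x sum(raw) for interior support."""
        rng = np.random.default_rng(8)
        kernel = SmoothingKernel(15)
        pts = rng.random((200, 3)) * (np.array(GRID) - 16) * 25.0 + 8 * 25.0
        maps = aggregate_to_voxels(plaques_at(pts), GRID)
        sm = smooth_spherical(maps["count"], kernel)
        assert sm.grid.sum() == pytest.approx(kernel.size * 200, rel=1e-9)

    def test_mean_smoothing_is_plaque_weighted(self):
        """Smoothed mean-size = sum(size x count)/sum(count) over the ROI,
        verified against a brute-force loop on a small kernel."""
        rng = np.random.default_rng(9)
        kernel = SmoothingKernel(5)
        pts = rng.random((60, 3)) * np.array(GRID) * 25.0
        vols = rng.uniform(100, 1000, 60)
        maps = aggregate_to_voxels(plaques_at(pts, volumes=vols), GRID)
        sm = smooth_spherical(maps["mean_size"], kernel)

        count = maps["count"].grid
        sums = np.where(np.isnan(maps["mean_size"].grid), 0.0,
                        maps["mean_size"].grid) * maps["mean_size"].weights
        offsets = np.argwhere(kernel.footprint) - 2
        for v in np.argwhere(count > 0)[:10]:
            neigh = v + offsets
            ok = np.all((neigh >= 0) & (neigh < np.array(GRID)), axis=1)
            n = count[tuple(neigh[ok].T)].sum()
            s = sums[tuple(neigh[ok].T)].sum()
            assert sm.grid[tuple(v)] == pytest.approx(s / n, rel=1e-9)

    def test_kernel_larger_than_volume_rejected(self):
        maps = aggregate_to_voxels(plaques_at([[10.0, 10.0, 10.0]]), (6, 6, 6))
        with pytest.raises(ValueError, match="kernel larger"):
            smooth_spherical(maps["count"], SmoothingKernel(15))

    def test_double_smoothing_rejected(self):
        maps = aggregate_to_voxels(plaques_at([[500.0, 500.0, 375.0]]), GRID)
        sm = smooth_spherical(maps["count"])
        with pytest.raises(ValueError, match="already smoothed"):
            smooth_spherical(sm)


def heatmaps_from(arrays, metric="count"):
    return [MetricHeatmap(np.asarray(a, dtype=float), metric, f"b{i}")
            for i, a in enumerate(arrays)]


class TestVoxelTTest:
    def test_single_voxel_matches_scalar_oracle(self):
        t = heatmaps_from([np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)])
        c = heatmaps_from([np.full((2, 2, 2), v) for v in (4.0, 5.0, 6.0)])
        comp = voxelwise_ttest(t, c)
        oracle = stats.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False).pvalue
        np.testing.assert_allclose(comp.p_map[comp.tested_mask], oracle, atol=1e-12)

    def test_group_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(10)
        shape = (8, 8, 6)
        t = heatmaps_from([rng.poisson(5, shape) + rng.random(shape) for _ in range(4)])
        c = heatmaps_from([rng.poisson(5, shape) + rng.random(shape) for _ in range(4)])
        a = voxelwise_ttest(t, c)
        b = voxelwise_ttest(c, t)
        np.testing.assert_allclose(a.p_map[a.tested_mask], b.p_map[b.tested_mask],
                                   atol=1e-12)
        np.testing.assert_array_equal(a.tested_mask, b.tested_mask)

    def test_identical_groups_excluded_or_p_one(self):
        arrs = [np.full((3, 3, 3), v) for v in (1.0, 2.0, 3.0)]
        comp = voxelwise_ttest(heatmaps_from(arrs), heatmaps_from(arrs))
        assert (~comp.tested_mask).all() or np.allclose(
            comp.p_map[comp.tested_mask], 1.0)

    def test_zero_variance_both_groups_excluded(self):
        t = heatmaps_from([np.full((2, 2, 2), 5.0)] * 3)
        c = heatmaps_from([np.full((2, 2, 2), 9.0)] * 3)
        comp = voxelwise_ttest(t, c)
        assert not comp.tested_mask.any()

    def test_too_few_brains_rejected(self):
        maps = heatmaps_from([np.zeros((2, 2, 2))])
        with pytest.raises(ValueError, match=">= 2 brains"):
            voxelwise_ttest(maps, maps * 2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            voxelwise_ttest(heatmaps_from([np.zeros((2, 2, 2))] * 2),
                            heatmaps_from([np.zeros((3, 3, 3))] * 2))


class TestBH:
    def test_hand_worked_stepup(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = adjust_bh(p, np.ones(4, bool))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.37]), np.ones(1, bool)),
                                   [0.37])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = rng.integers(1, 2000)
            p = rng.random(n) ** rng.uniform(0.3, 3)
            adj = adjust_bh(p, np.ones(n, bool))
            np.testing.assert_allclose(adj, bh_stepup_oracle(p), atol=1e-12)
            assert np.all(adj >= p - 1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200),
           st.floats(min_value=0.01, max_value=0.2))
    def test_threshold_selects_bh_rejection_set(self, p_list, alpha):
        """Thresholding adjusted p at alpha reproduces the classic step-up
        rejection rule: reject the k largest-index sorted p with p_(k) <= k alpha/m."""
        p = np.array(p_list)
        adj = adjust_bh(p, np.ones(len(p), bool))
        order = np.argsort(p, kind="mergesort")
        thresh = np.arange(1, len(p) + 1) * alpha / len(p)
        passing = np.nonzero(p[order] <= thresh)[0]
        reject_oracle = np.zeros(len(p), bool)
        if len(passing):
            reject_oracle[order[: passing[-1] + 1]] = True
        np.testing.assert_array_equal(adj <= alpha, reject_oracle)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]), np.ones(2, bool))

    def test_respects_tested_mask(self):
        p = np.array([0.01, np.nan, 0.04])
        mask = np.array([True, False, True])
        adj = adjust_bh(p, mask)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], bh_stepup_oracle(p[[0, 2]]))


class TestSAV:
    def test_all_p_one_gives_empty_sav(self):
        t = heatmaps_from([np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)])
        comp = voxelwise_ttest(t, t[::-1])
        assert binarize_sav(comp, 0.05).count == 0

    def test_threshold_nesting(self, planted_cohort_analysis):
        a = planted_cohort_analysis
        assert not (a.sav05.grid & ~a.sav10.grid).any()
        assert a.sav05.count <= a.sav10.count

    def test_sav_subset_of_tested(self, planted_cohort_analysis):
        a = planted_cohort_analysis
        assert not (a.sav05.grid & ~a.comparison.tested_mask).any()

    def test_invalid_alpha_rejected(self, planted_cohort_analysis):
        with pytest.raises(ValueError):
            binarize_sav(planted_cohort_analysis.comparison, 1.5)

    def test_planted_effect_recovered(self, planted_cohort_analysis):
        """Sensitivity >= 0.8 inside the planted sphere; false positives
        beyond the smoothing-dilated sphere bounded by alpha."""
        a = planted_cohort_analysis
        sens = (a.sav05.grid & a.inside).sum() / a.inside.sum()
        fp = (a.sav05.grid & a.far).sum() / max((a.comparison.tested_mask & a.far).sum(), 1)
        assert sens >= 0.8
        assert fp <= 0.05

    def test_null_calibration(self, null_cohort_analysis):
        """No planted effect: raw-p rejection at 0.05 stays near nominal."""
        comp = null_cohort_analysis.comparison
        rate = np.mean(comp.p_map[comp.tested_mask] < 0.05)
        assert rate == pytest.approx(0.05, abs=0.02)


class TestRegionStats:
    def _one_region_atlas(self):
        import pandas as pd
        labels = np.ones((10, 10, 10), dtype=np.int32)
        table = pd.DataFrame([{"label": 1, "acronym": "ALL", "name": "whole brain"}])
        from q3d import AtlasVolume
        return AtlasVolume(labels=labels, region_table=table)

    def test_single_region_density_is_total_over_volume(self):
        atlas = self._one_region_atlas()
        rng = np.random.default_rng(14)
        brains = []
        for i in range(4):
            pts = rng.random((50, 3)) * 250.0
            group = "control" if i < 2 else "treated"
            brains.append((f"b{i}", group, plaques_at(pts)))
        df = region_stats(brains, atlas)
        brain_vol_mm3 = 1000 * (25.0 / 1000) ** 3
        assert df["density_control"].iloc[0] == pytest.approx(50 / brain_vol_mm3)

    def test_group_swap_leaves_p_unchanged(self):
        atlas = self._one_region_atlas()
        rng = np.random.default_rng(15)
        brains = []
        for i in range(6):
            pts = rng.random((30 + 5 * i, 3)) * 250.0
            group = "control" if i < 3 else "treated"
            brains.append((f"b{i}", group, plaques_at(pts)))
        swapped = [(b, {"control": "treated", "treated": "control"}[g], t)
                   for b, g, t in brains]
        df1 = region_stats(brains, atlas)
        df2 = region_stats(swapped, atlas)
        np.testing.assert_allclose(df1["density_p"], df2["density_p"], atol=1e-12)

    def test_planted_region_attains_minimum_p(self, toy_atlas):
        """A count effect confined to one toy-atlas region should make that
        region the family's most significant."""
        target = 9  # central core
        core_vox = np.argwhere(toy_atlas.labels == target)
        center = core_vox.mean(axis=0)
        radius = 1.1 * np.max(np.linalg.norm(core_vox - center, axis=1))
        phantom = PhantomSpec(shape=(369, 369, 300), n_plaques=4000, seed=0)
        eff = EffectRegionSpec(center_vox=tuple(center), radius_vox=float(radius),
                               affected_metric="count", effect_size=0.2)
        brains = generate_cohort(
            CohortSpec(n_control=5, n_treated=5, phantom=phantom, effects=[eff],
                       inter_brain_cv=0.05, seed=21))
        df = region_stats([(b.brain_id, b.group, b.truth) for b in brains], toy_atlas)
        assert df.loc[df["density_p"].idxmin(), "label"] == target
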