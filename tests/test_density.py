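"""kNN area-density estimation, rendering, and map comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stain3d import density as dens
from stain3d.synthetic import PointPatternSpec, generate_point_pattern
from stain3d.types import CellPoints, DensityGrid


def brute_force_density(node, points, k=8):
    """Independent oracle: enumerate all distances, sort, apply the
    mean-squared-distance formula directly."""
    d = np.hypot(points[:, 0] - node[0], points[:, 1] - node[1])
    dk = np.sort(d)[:k]
    return k / (np.pi * np.mean(dk**2))


class TestKnnDensity:
    def test_closed_form_when_all_neighbors_equidistant(self):
        # 8 points on a circle of radius d around the single grid node
        d = 0.3
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = CellPoints(1.0 + d * np.cos(ang), 1.0 + d * np.sin(ang))
        grid = dens.knn_density(pts, spacing=1.0, origin=(1.0, 1.0), shape=(1, 1),
                                region=(2.0, 2.0))
        assert grid.values[0, 0] == pytest.approx(8 / (np.pi * d**2), rel=1e-12)

    def test_regular_lattice_matches_brute_force_and_true_density(self):
        s = 0.1
        xx, yy = np.meshgrid(np.arange(30) * s, np.arange(30) * s)
        pts = CellPoints(xx.ravel(), yy.ravel())
        # at a cell-centered node the 8 NN sit at s/sqrt(2) (x4) and
        # s*sqrt(5/2) (x4), so mean d^2 = 1.5 s^2 exactly
        analytic = 8 / (np.pi * 1.5 * s**2)
        nodes = [(1.45, 1.45), (1.05, 1.55), (1.55, 1.05)]
        for node in nodes:
            grid = dens.knn_density(pts, spacing=1.0, origin=node, shape=(1, 1),
                                    region=(2.9, 2.9))
            oracle = brute_force_density(node, pts.coordinates)
            assert grid.values[0, 0] == pytest.approx(oracle, rel=1e-9)
            assert grid.values[0, 0] == pytest.approx(analytic, rel=1e-9)
            corrected = dens.knn_density(pts, spacing=1.0, origin=node,
                                         shape=(1, 1), region=(2.9, 2.9),
                                         bias_correction=True)
            # after removing the finite-k factor the estimate approaches the
            # true lattice density 1/s^2
            assert corrected.values[0, 0] == pytest.approx(1 / s**2, rel=0.15)

    def test_homogeneous_poisson_median_matches_calibrated_bias(self):
        lam = 500.0
        meds = []
        for seed in range(20):
            pts, _ = generate_point_pattern(
                PointPatternSpec(region=(2.0, 2.0), intensity=lam, seed=seed)
            )
            grid = dens.knn_density(pts, spacing=0.1, origin=(0.4, 0.4),
                                    shape=(13, 13), region=(1.2, 1.2))
            meds.append(np.nanmedian(grid.values))
        factor = dens.knn_bias_factor(8)
        assert np.median(meds) / lam == pytest.approx(factor, rel=0.10)

    def test_bias_correction_flag_recenters_on_truth(self):
        lam = 500.0
        meds = []
        for seed in range(10):
            pts, _ = generate_point_pattern(
                PointPatternSpec(region=(2.0, 2.0), intensity=lam, seed=seed)
            )
            grid = dens.knn_density(pts, spacing=0.1, origin=(0.4, 0.4),
                                    shape=(13, 13), region=(1.2, 1.2),
                                    bias_correction=True)
            meds.append(np.nanmedian(grid.values))
        assert np.median(meds) == pytest.approx(lam, rel=0.10)

    def test_alternative_convention_differs_by_factor_k(self):
        pts, _ = generate_point_pattern(
            PointPatternSpec(region=(1.0, 1.0), intensity=300.0, seed=0)
        )
        a = dens.knn_density(pts, spacing=0.2, shape=(4, 4))
        b = dens.knn_density(pts, spacing=0.2, shape=(4, 4), per_cell_area=False)
        np.testing.assert_allclose(a.values, 8.0 * b.values, rtol=1e-12)

    def test_too_few_points_warns_and_returns_missing(self):
        pts = CellPoints([0.1, 0.2], [0.1, 0.2])
        with pytest.warns(UserWarning, match="missing"):
            grid = dens.knn_density(pts, spacing=0.1)
        assert np.isnan(grid.values).all()

    @settings(max_examples=10, deadline=None)
    @given(c=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_law_one_over_c_squared(self, c):
        pts, _ = generate_point_pattern(
            PointPatternSpec(region=(1.0, 1.0), intensity=200.0, seed=1)
        )
        base = dens.knn_density(pts, spacing=0.25, origin=(0.25, 0.25), shape=(3, 3),
                                region=(0.5, 0.5))
        scaled_pts = CellPoints(c * pts.x, c * pts.y)
        scaled = dens.knn_density(scaled_pts, spacing=c * 0.25,
                                  origin=(c * 0.25, c * 0.25), shape=(3, 3),
                                  region=(c * 0.5, c * 0.5))
        np.testing.assert_allclose(scaled.values, base.values / c**2, rtol=1e-9)

    def test_adding_interior_point_never_decreases_density(self):
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        x = 1.0 + 0.5 * np.cos(ang)
        y = 1.0 + 0.5 * np.sin(ang)
        before = dens.knn_density(CellPoints(x, y), spacing=1.0, origin=(1.0, 1.0),
                                  shape=(1, 1), region=(2.0, 2.0)).values[0, 0]
        x2 = np.append(x, 1.1)
        y2 = np.append(y, 1.0)
        after = dens.knn_density(CellPoints(x2, y2), spacing=1.0, origin=(1.0, 1.0),
                                 shape=(1, 1), region=(2.0, 2.0)).values[0, 0]
        assert after >= before

    def test_translation_invariance(self):
        pts, _ = generate_point_pattern(
            PointPatternSpec(region=(1.0, 1.0), intensity=300.0, seed=2)
        )
        base = dens.knn_density(pts, spacing=0.2, origin=(0.2, 0.2), shape=(3, 3),
                                region=(0.6, 0.6))
        shift = (1.7, -0.4)
        moved = dens.knn_density(
            CellPoints(pts.x + shift[0], pts.y + shift[1]),
            spacing=0.2, origin=(0.2 + shift[0], 0.2 + shift[1]), shape=(3, 3),
            region=(0.6, 0.6),
        )
        np.testing.assert_allclose(moved.values, base.values, rtol=1e-12)

    def test_edge_biased_nodes_flagged(self):
        pts, _ = generate_point_pattern(
            PointPatternSpec(region=(2.0, 2.0), intensity=30.0, seed=3)
        )
        grid = dens.knn_density(pts, spacing=0.25, origin=(0.0, 0.0), shape=(9, 9),
                                region=(2.0, 2.0))
        assert grid.edge_biased is not None
        assert grid.edge_biased[0, 0]  # corner node: k-th neighbor beyond boundary


class TestRenderDensity:
    def grid(self, values):
        return DensityGrid(origin=(0, 0), spacing=0.5, values=np.asarray(values, float))

    def test_display_floor_and_ceiling(self):
        img = dens.render_density(self.grid([[29.0, 30.0, 1200.0, 1500.0]]))
        assert tuple(img[0, 0]) == (0, 0, 0)
        assert tuple(img[0, 1]) == (0, 0, 0)
        assert tuple(img[0, 2]) == (255, 255, 255)
        assert tuple(img[0, 3]) == (255, 255, 255)

    def test_linear_gray_mapping(self):
        img = dens.render_density(self.grid([[615.0]]))
        expected = round(255 * (615 - 30) / 1170)
        assert tuple(img[0, 0]) == (expected,) * 3

    def test_missing_nodes_get_sentinel_color(self):
        img = dens.render_density(self.grid([[np.nan, 600.0]]))
        assert tuple(img[0, 0]) == dens.MISSING_RGB
        assert img[0, 1, 0] == img[0, 1, 1] == img[0, 1, 2]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            dens.render_density(self.grid([[1.0]]), floor=100.0, ceiling=50.0)


class TestCompareDensity:
    def make(self, values):
        return DensityGrid(origin=(0, 0), spacing=0.5, values=np.asarray(values, float))

    def test_self_comparison_is_null(self):
        g = self.make([[100.0, 200.0], [300.0, 400.0]])
        diff, ratio, summary = dens.compare_density(g, g)
        np.testing.assert_allclose(diff, 0.0)
        np.testing.assert_allclose(ratio, 1.0)
        assert summary.loc[0, "mean_difference"] == 0.0

    def test_doubled_map_has_ratio_two(self):
        g = self.make([[100.0, 200.0]])
        h = self.make([[200.0, 400.0]])
        _, ratio, _ = dens.compare_density(g, h)
        np.testing.assert_allclose(ratio, 2.0)

    def test_geometry_mismatch_rejected(self):
        g = self.make([[1.0]])
        h = DensityGrid(origin=(0, 0), spacing=0.25, values=np.array([[1.0]]))
        with pytest.raises(ValueError, match="geometry"):
            dens.compare_density(g, h)

    def test_halved_subregion_intensity_shows_in_region_ratio(self):
        # pattern B has half the density of A inside a marked subregion
        lam = 600.0
        ratios = []
        for seed in range(20):
            lam_map_a = np.full((32, 32), lam)
            lam_map_b = lam_map_a.copy()
            lam_map_b[:, 16:] = lam / 2  # right half (x > 2 mm)
            pa, _ = generate_point_pattern(
                PointPatternSpec(region=(4.0, 4.0), intensity=lam_map_a, seed=seed)
            )
            pb, _ = generate_point_pattern(
                PointPatternSpec(region=(4.0, 4.0), intensity=lam_map_b, seed=seed + 1000)
            )
            kw = dict(spacing=0.25, origin=(0.5, 0.5), shape=(13, 13), region=(3.0, 3.0))
            ga = dens.knn_density(pa, **kw)
            gb = dens.knn_density(pb, **kw)
            labels = np.zeros((13, 13), dtype=int)
            labels[:, ga.node_x > 2.3] = 1  # interior of the halved region
            _, _, summary = dens.compare_density(ga, gb, labels=labels)
            row = summary.set_index("region").loc["1"]
            # ratio of region means: the pointwise mean-of-ratios is
            # Jensen-biased upward for noisy finite-k estimates
            ratios.append(row["mean_b"] / row["mean_a"])
        assert np.mean(ratios) == pytest.approx(0.5, rel=0.15)


def test_bias_factor_statistics_are_stable():
    med = dens.knn_bias_factor(8, statistic="median")
    mean = dens.knn_bias_factor(8, statistic="mean")
    assert 1.7 < med < 2.1
    assert mean > med
    with pytest.raises(ValueError):
        dens.knn_bias_factor(8, statistic="mode")
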