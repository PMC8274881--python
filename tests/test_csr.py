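"""Quadrat, Hopkins-Skellam and scan tests of Complete Spatial Randomness."""

import numpy as np
import pytest

from lithospat import hopkins_skellam, quadrat_test, scan_test
from lithospat import synthetic as syn
from lithospat.csr import (
    ScanGeometry,
    _scan_lrt_max,
    equal_area_cuts,
    mc_p_value,
    prepare_scan,
)
from lithospat.geometry import Window, build_pattern


class TestRankPValues:
    def test_p_values_are_multiples_of_one_over_nsim_plus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            null = rng.normal(size=19)
            p = mc_p_value(rng.normal(), null)
            assert round(p * 20) == pytest.approx(p * 20, abs=1e-12)
            assert 0 < p <= 1

    def test_minimum_attainable_p_with_19_sims(self):
        assert mc_p_value(100.0, np.arange(19.0)) == 0.05


class TestQuadratTest:
    def test_perfect_uniformity_gives_zero(self, unit_square):
        # 20 points in each of 5 equal-area vertical slabs
        cuts = equal_area_cuts(unit_square, 5)
        xs = np.concatenate([np.linspace(lo + 0.01, hi - 0.01, 20)
                             for lo, hi in zip([0, *cuts], [*cuts, 1])])
        pp = build_pattern(np.column_stack([xs, np.full(100, 0.5)]), unit_square)
        res = quadrat_test(pp, 5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_all_points_in_one_tile(self, unit_square):
        # X^2 = (100-20)^2/20 + 4*(0-20)^2/20 = 400
        rng = np.random.default_rng(1)
        coords = np.column_stack([rng.uniform(0, 0.19, 100), rng.uniform(0, 1, 100)])
        res = quadrat_test(build_pattern(coords, unit_square), 5)
        assert res.statistic == pytest.approx(400.0)
        assert res.df == 4

    def test_statistic_invariant_to_tile_relabeling(self, csr_pattern):
        # mirroring the pattern permutes the tiles but not the statistic
        mirrored = build_pattern(
            np.column_stack([1 - csr_pattern.coords[:, 0], csr_pattern.coords[:, 1]]),
            csr_pattern.window,
        )
        assert quadrat_test(csr_pattern, 5).statistic == pytest.approx(
            quadrat_test(mirrored, 5).statistic
        )

    def test_equal_area_cuts_on_irregular_window(self):
        w = syn.ds_window()
        cuts = equal_area_cuts(w, 5)
        from shapely.geometry import box

        xmin = w.bounds[0]
        cums = [
            w.polygon.intersection(box(xmin - 1, -100, hi, 100)).area
            for hi in [*cuts, w.bounds[2]]
        ]
        areas = np.diff([0.0, *cums])
        np.testing.assert_allclose(areas, w.area_m2 / 5, rtol=1e-6)

    def test_too_few_points_rejected(self, unit_square):
        pp = build_pattern([(0.5, 0.5)], unit_square)
        with pytest.raises(ValueError):
            quadrat_test(pp, 5)


class TestHopkinsSkellam:
    def test_csr_statistic_near_one(self, unit_square):
        from lithospat.csr import hopkins_skellam_statistic

        vals = [
            hopkins_skellam_statistic(
                syn.csr_fixed_n(500, unit_square, 100 + s), 100,
                np.random.default_rng(200 + s),
            )
            for s in range(200)
        ]
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_clustered_pattern_detected(self, unit_square):
        """Thomas clusters inflate empty-space distances: A >> 1."""
        sig = 0
        n_tot = 0
        for s in range(100):
            pp = syn.rthomas(10, 50, 0.02, unit_square, 300 + s)
            if pp.n < 10:
                continue
            n_tot += 1
            res = hopkins_skellam(pp, n_sample=50, seed=400 + s, n_sim=19)
            if res.statistic > 1 and res.p_value <= 0.05:
                sig += 1
        assert sig / n_tot >= 0.95

    def test_regular_grid_gives_a_below_one(self, unit_square):
        from lithospat.csr import hopkins_skellam_statistic

        g = (np.arange(20) + 0.5) / 20
        xx, yy = np.meshgrid(g, g)
        rng = np.random.default_rng(5)
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        coords = np.clip(coords + rng.normal(0, 0.003, coords.shape), 0, 1)
        pp = build_pattern(coords, unit_square)
        vals = [
            hopkins_skellam_statistic(pp, 100, np.random.default_rng(600 + s))
            for s in range(50)
        ]
        assert np.mean(vals) < 1.0

    def test_oversampling_warns(self, unit_square):
        pp = syn.csr_fixed_n(20, unit_square, 7)
        with pytest.warns(UserWarning, match="replacement"):
            hopkins_skellam(pp, n_sample=40, seed=8, n_sim=9)


class TestScanTest:
    def test_lrt_formula_all_points_in_half_area_circle(self):
        """All n points inside one circle of clipped area |W|/2: 2 n log 2."""
        rng = np.random.default_rng(2)
        coords = rng.uniform(0.45, 0.55, (100, 2))
        geom = ScanGeometry(
            Window.unit_square(), 0.2,
            centers=np.array([[0.5, 0.5]]),
            expected_fraction=np.array([0.5]),
        )
        _, stat, _ = _scan_lrt_max(coords, geom)
        assert stat == pytest.approx(2 * 100 * np.log(2), rel=1e-12)

    def test_lrt_zero_when_no_excess(self):
        geom = ScanGeometry(
            Window.unit_square(), 0.2,
            centers=np.array([[0.5, 0.5]]),
            expected_fraction=np.array([0.5]),
        )
        coords = np.array([[0.01, 0.01], [0.99, 0.99], [0.02, 0.97]])
        lrt, stat, _ = _scan_lrt_max(coords, geom)
        assert stat == 0.0

    def test_tiny_radius_gives_p_one(self, unit_square):
        pp = build_pattern([(0.2, 0.2), (0.8, 0.8)], unit_square)
        res = scan_test(pp, radius=0.01, n_sim=9, seed=1, pixel=1 / 8)
        assert res.statistic == 0.0 or res.p_value >= 0.9

    def test_implanted_cluster_located(self, unit_square):
        """Max-LRT location lands within r of an implanted dense disc."""
        geom = prepare_scan(unit_square, 0.1, pixel=1 / 24)
        hits, total = 0, 30
        centre = np.array([0.35, 0.6])
        for s in range(total):
            rng = np.random.default_rng(800 + s)
            bg = rng.uniform(0, 1, (80, 2))
            ang = rng.uniform(0, 2 * np.pi, 60)
            rad = 0.08 * np.sqrt(rng.uniform(0, 1, 60))
            disc = centre + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            pp = build_pattern(np.clip(np.vstack([bg, disc]), 0, 1), unit_square)
            res = scan_test(pp, 0.1, n_sim=9, seed=900 + s, geometry=geom)
            if np.hypot(*(res.location - centre)) <= 0.1:
                hits += 1
        assert hits / total >= 0.9

    def test_reported_maximum_is_attained_at_location(self, csr_pattern):
        res = scan_test(csr_pattern, 0.15, n_sim=9, seed=3, pixel=1 / 16)
        k = np.argmax(res.lrt)
        np.testing.assert_array_equal(res.location, res.centers[k])
        assert res.statistic == res.lrt[k]
        assert (res.lrt >= 0).all()
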