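"""Kernel intensity estimation and bandwidth selection."""

import math

import numpy as np
import pytest

from lithospat import (
    bw_cronie_vanlieshout,
    bw_likelihood_cv,
    kernel_intensity,
    subtract_maps,
)
from lithospat import synthetic as syn
from lithospat.geometry import Window, build_pattern
from lithospat.intensity import raster_grid


class TestKernelIntensity:
    def test_single_point_mass_conservation(self, unit_square):
        pp = build_pattern([(0.5, 0.5)], unit_square)
        imap = kernel_intensity(pp, bandwidth=0.1, pixel=0.1 / 4)
        assert imap.integral() == pytest.approx(1.0, rel=0.01)

    def test_integral_close_to_n_for_any_pattern(self, csr_pattern):
        imap = kernel_intensity(csr_pattern, bandwidth=0.08, pixel=0.02)
        assert imap.integral() == pytest.approx(csr_pattern.n, rel=0.02)

    def test_grid_node_equals_brute_force_kernel_sum(self, csr_pattern):
        h = 0.07
        imap = kernel_intensity(csr_pattern, h, pixel=1 / 32, edge_correction=False)
        xs, ys = imap.grid_coords()
        for i, j in [(3, 5), (16, 20), (30, 2)]:
            bf = sum(
                math.exp(-((xs[j] - x) ** 2 + (ys[i] - y) ** 2) / (2 * h * h))
                / (2 * math.pi * h * h)
                for x, y in csr_pattern.coords
            )
            assert abs(imap.values[i, j] - bf) < 1e-10

    def test_homogeneous_mean_recovers_intensity(self, unit_square):
        lam, means = 100.0, []
        for s in range(50):
            pp = syn.rpoispp(lam, unit_square, 2000 + s)
            imap = kernel_intensity(pp, 0.1, pixel=1 / 48)
            means.append(np.nanmean(imap.values))
        assert np.mean(means) == pytest.approx(lam, rel=0.05)

    def test_empty_pattern_rejected(self, unit_square):
        pp = build_pattern([], unit_square)
        with pytest.raises(ValueError):
            kernel_intensity(pp, 0.1)

    def test_monotone_smoothing(self, csr_pattern):
        hs = np.geomspace(0.03, 0.4, 8)
        variances = [
            np.nanvar(kernel_intensity(csr_pattern, h, pixel=1 / 48).values)
            for h in hs
        ]
        assert (np.diff(variances) <= 1e-9).all()

    def test_no_boundary_depression(self, unit_square):
        """Uniform edge correction removes the boundary deficit."""
        ratios = []
        for s in range(30):
            pp = syn.rpoispp(150, unit_square, 3000 + s)
            imap = kernel_intensity(pp, 0.08, pixel=1 / 48)
            xs, ys = imap.grid_coords()
            xx, yy = np.meshgrid(xs, ys)
            bd = np.minimum.reduce([xx, 1 - xx, yy, 1 - yy])
            strip = (bd < 0.05) & imap.mask
            inner = (bd >= 0.2) & imap.mask
            ratios.append(np.nanmean(imap.values[strip]) / np.nanmean(imap.values[inner]))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


class TestBandwidthSelection:
    def test_lcv_is_deterministic(self, csr_pattern):
        grid = np.geomspace(0.02, 0.3, 8)
        a = bw_likelihood_cv(csr_pattern, grid)
        b = bw_likelihood_cv(csr_pattern, grid)
        assert a.selected == b.selected
        np.testing.assert_array_equal(a.objective, b.objective)

    def test_singleton_grid_returned(self, csr_pattern):
        sel = bw_likelihood_cv(csr_pattern, [0.12])
        assert sel.selected == 0.12

    def test_selected_is_argmax_of_trace(self, csr_pattern):
        sel = bw_likelihood_cv(csr_pattern, np.geomspace(0.02, 0.3, 8))
        assert sel.selected == sel.h_grid[np.argmax(sel.objective)]

    def test_lcv_tracks_thomas_cluster_scale(self, unit_square):
        """Selected h lands within [sigma/3, 3 sigma] for clustered data."""
        sigma, hits, total = 0.05, 0, 0
        grid = np.geomspace(0.01, 0.3, 12)
        for s in range(50):
            pp = syn.rthomas(15, 25, sigma, unit_square, 4000 + s)
            if pp.n < 20:
                continue
            total += 1
            sel = bw_likelihood_cv(pp, grid, pixel=1 / 32)
            if sigma / 3 <= sel.selected <= 3 * sigma:
                hits += 1
        assert hits / total >= 0.8

    def test_cvl_discrepancy_matches_hand_evaluation(self, unit_square):
        """5-point toy: objective equals |sum 1/lambda_h(x_i) - |W|| directly."""
        coords = np.array([[0.2, 0.2], [0.8, 0.3], [0.5, 0.5], [0.3, 0.8], [0.7, 0.7]])
        pp = build_pattern(coords, unit_square)
        h = 0.25
        sel = bw_cronie_vanlieshout(pp, [h], pixel=1 / 64)
        # hand evaluation with the same discrete edge-correction quadrature
        from lithospat.intensity import _edge_grid, _edge_at

        xs, ys, mask = raster_grid(unit_square, 1 / 64)
        cg = _edge_grid(mask, h, 1 / 64)
        c = _edge_at(cg, coords, 0.0, 0.0, 1 / 64)
        lam = np.empty(5)
        for i in range(5):
            d2 = ((coords[i] - coords) ** 2).sum(1)
            lam[i] = (np.exp(-d2 / (2 * h * h)) / (2 * np.pi * h * h)).sum() / c[i]
        assert sel.objective[0] == pytest.approx(abs((1 / lam).sum() - 1.0), abs=1e-9)

    def test_cvl_selected_is_argmin(self, csr_pattern):
        sel = bw_cronie_vanlieshout(csr_pattern, np.geomspace(0.03, 0.3, 6))
        assert sel.selected == sel.h_grid[np.argmin(sel.objective)]

    def test_near_flat_estimate_gives_small_discrepancy(self, unit_square):
        # with a huge bandwidth the estimate is ~flat = n/|W|, so
        # sum(1/lambda) ~ |W| and the criterion approaches zero
        pp = syn.rpoispp(100, unit_square, 8)
        sel = bw_cronie_vanlieshout(pp, [5.0], pixel=1 / 32)
        assert sel.objective[0] < 0.05


class TestSubtractMaps:
    def test_self_subtraction_is_zero(self, csr_pattern):
        a = kernel_intensity(csr_pattern, 0.1, pixel=1 / 32)
        d = subtract_maps(a, a)
        assert np.nanmax(np.abs(d.values)) == 0.0

    def test_subtract_then_add_recovers(self, csr_pattern):
        a = kernel_intensity(csr_pattern, 0.1, pixel=1 / 32)
        b = kernel_intensity(csr_pattern, 0.2, pixel=1 / 32)
        d = subtract_maps(a, b)
        back = d.values + b.values
        np.testing.assert_allclose(back[a.mask], a.values[a.mask], atol=1e-12)

    def test_grid_mismatch_rejected(self, csr_pattern):
        a = kernel_intensity(csr_pattern, 0.1, pixel=1 / 32)
        b = kernel_intensity(csr_pattern, 0.1, pixel=1 / 16)
        with pytest.raises(ValueError):
            subtract_maps(a, b)

    def test_identically_distributed_labelings_nearly_cancel(self, unit_square):
        """Density maps of two random halves of one pattern almost cancel."""
        diffs, scale = [], []
        for s in range(10):
            pp = syn.rpoispp(400, unit_square, 6000 + s)
            rng = np.random.default_rng(7000 + s)
            half = rng.permutation(pp.n) < pp.n // 2
            a = kernel_intensity(pp.subset(np.flatnonzero(half)), 0.15, pixel=1 / 32)
            b = kernel_intensity(pp.subset(np.flatnonzero(~half)), 0.15, pixel=1 / 32)
            d = subtract_maps(a, b)
            diffs.append(np.nanmean(np.abs(d.values)))
            scale.append(np.nanmean(a.values))
        assert np.mean(diffs) < 0.5 * np.mean(scale)
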