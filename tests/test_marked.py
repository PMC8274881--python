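"""Type probabilities, tolerance contours, segregation, NN equality."""

import numpy as np
import pytest

from lithospat import nn_equality, segregation_test, tolerance_contours, type_probability
from lithospat import synthetic as syn
from lithospat.geometry import build_pattern
from lithospat.marked import _kernel_matrix


class TestTypeProbability:
    def test_duplicated_coordinates_give_half_everywhere(self, unit_square):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.05, 0.95, (40, 2))
        coords = np.vstack([base, base])
        pp = build_pattern(coords, unit_square, {"type": ["a"] * 40 + ["b"] * 40})
        field = type_probability(pp, "type", bandwidth=0.1, pixel=1 / 16)
        np.testing.assert_allclose(field.prob("a")[field.mask], 0.5, atol=1e-12)

    def test_probabilities_sum_to_one(self, unit_square):
        pp = syn.rpoispp(200, unit_square, 2)
        pp = syn.label_random(pp, {"a": 0.5, "b": 0.3, "c": 0.2}, 3)
        field = type_probability(pp, "type", bandwidth=0.1, pixel=1 / 24)
        total = field.probs[:, field.mask].sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert field.proportions.sum() == pytest.approx(1.0)

    def test_single_pixel_matches_kernel_sum_ratio(self, unit_square):
        pp = syn.rpoispp(80, unit_square, 4)
        pp = syn.label_random(pp, {"a": 0.6, "b": 0.4}, 5)
        h = 0.12
        field = type_probability(pp, "type", bandwidth=h, pixel=1 / 8)
        xs, ys = np.arange(8) / 8 + 1 / 16, np.arange(8) / 8 + 1 / 16
        i, j = 3, 5
        centre = np.array([[xs[j], ys[i]]])
        k = _kernel_matrix(centre, pp.coords, h)[0]
        is_a = pp.mark("type") == "a"
        expect = k[is_a].sum() / k.sum()
        assert field.prob("a")[i, j] == pytest.approx(expect, abs=1e-12)

    def test_random_labeling_recovers_proportions(self, unit_square):
        means = []
        for s in range(50):
            pp = syn.rpoispp(150, unit_square, 100 + s)
            pp = syn.label_random(pp, {"a": 0.7, "b": 0.3}, 200 + s)
            if (pp.mark("type") == "a").sum() < 1 or (pp.mark("type") == "b").sum() < 1:
                continue
            field = type_probability(pp, "type", bandwidth=0.15, pixel=1 / 16)
            means.append(np.nanmean(field.prob("a")))
        assert np.mean(means) == pytest.approx(0.70, abs=0.03)

    def test_single_type_rejected(self, unit_square):
        pp = syn.rpoispp(50, unit_square, 6)
        pp = syn.label_random(pp, {"a": 1.0}, 7)
        with pytest.raises(ValueError):
            type_probability(pp, "type", bandwidth=0.1)


class TestToleranceContours:
    def test_unattainable_alpha_rejected(self, two_cluster_pattern):
        with pytest.raises(ValueError, match="unattainable"):
            tolerance_contours(two_cluster_pattern, "type", 0.1, n_sim=9, alpha=0.05)

    def test_null_masked_fraction_near_alpha(self, unit_square):
        fracs = []
        for s in range(50):
            pp = syn.rpoispp(250, unit_square, 300 + s)
            pp = syn.label_random(pp, {"a": 0.5, "b": 0.5}, 400 + s)
            f = tolerance_contours(pp, "type", 0.1, n_sim=19, seed=500 + s, pixel=1 / 24)
            fracs.append(f.sig_masks[:, f.mask].mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.03)

    def test_pure_cluster_cores_enter_own_masks(self, unit_square):
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(600 + s)
            c1 = np.clip(rng.normal([0.25, 0.5], 0.07, (60, 2)), 0.001, 0.999)
            c2 = np.clip(rng.normal([0.75, 0.5], 0.07, (60, 2)), 0.001, 0.999)
            pp = build_pattern(np.vstack([c1, c2]), unit_square,
                               {"type": ["a"] * 60 + ["b"] * 60})
            f = tolerance_contours(pp, "type", 0.08, n_sim=19, seed=700 + s, pixel=1 / 32)
            ma, mb = f.sig_mask("a"), f.sig_mask("b")
            if ma[int(0.5 * 32), int(0.25 * 32)] and mb[int(0.5 * 32), int(0.75 * 32)]:
                hits += 1
        assert hits / 40 >= 0.95

    def test_minimum_pixel_p_is_one_twentieth(self, two_cluster_pattern):
        """19 relabelings make 0.05 the smallest attainable pixel p."""
        f = tolerance_contours(two_cluster_pattern, "type", 0.08, n_sim=19,
                               alpha=0.05, seed=1, pixel=1 / 16)
        assert f.alpha == 0.05
        assert f.n_sim == 19
        # masks are exactly the pixels whose rank p equals 1/20
        assert f.sig_masks.any()


class TestSegregationTest:
    def test_statistic_invariant_to_type_renaming(self, two_cluster_pattern):
        res_ab = segregation_test(two_cluster_pattern, "type", 0.08, n_sim=9, seed=1)
        swapped = two_cluster_pattern.with_marks(
            {"type": np.where(two_cluster_pattern.mark("type") == "a", "b", "a")}
        )
        res_ba = segregation_test(swapped, "type", 0.08, n_sim=9, seed=1)
        assert res_ab.statistic == pytest.approx(res_ba.statistic, rel=1e-12)

    def test_fully_segregated_hits_minimum_p(self, two_cluster_pattern):
        res = segregation_test(two_cluster_pattern, "type", 0.08, n_sim=19, seed=2)
        assert res.p_value == 0.05

    def test_perfectly_mixed_duplicates_not_significant(self, unit_square):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.05, 0.95, (50, 2))
        pp = build_pattern(np.vstack([base, base]), unit_square,
                           {"type": ["a"] * 50 + ["b"] * 50})
        res = segregation_test(pp, "type", 0.1, n_sim=19, seed=9)
        assert res.p_value > 0.5
        # statistic sits at or below the null median for perfect mixing
        assert res.statistic <= np.median(res.null_values)

    def test_type_with_one_point_rejected(self, unit_square):
        pp = syn.rpoispp(50, unit_square, 10)
        marks = np.array(["a"] * (pp.n - 1) + ["b"], dtype=object)
        with pytest.raises(ValueError):
            segregation_test(pp.with_marks({"type": marks}), "type", 0.1)

    def test_relabeling_preserves_label_multiset(self, two_cluster_pattern):
        perm = syn.permute_mark(two_cluster_pattern, "type", 3)
        a, b = np.unique(perm.mark("type"), return_counts=True)[1], [60, 60]
        np.testing.assert_array_equal(sorted(a), sorted(b))


class TestNNEquality:
    def test_alternating_line_first_neighbour_is_other_type(self, unit_square):
        xs = np.linspace(0.1, 0.9, 6)
        pp = build_pattern(
            np.column_stack([xs, np.full(6, 0.5)]), unit_square,
            {"type": ["a", "b", "a", "b", "a", "b"]},
        )
        cur = nn_equality(pp, "type", "a", "b", k_max=1, n_sim=9, seed=1)
        assert cur.observed[0] == 1.0

    def test_curves_over_target_types_sum_to_one(self, unit_square):
        pp = syn.rpoispp(150, unit_square, 11)
        pp = syn.label_random(pp, {"a": 0.4, "b": 0.35, "c": 0.25}, 12)
        total = np.zeros(6)
        for to in ("a", "b", "c"):
            total += nn_equality(pp, "type", "a", to, k_max=6, n_sim=1, seed=1).observed
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_pure_separated_clusters_cumulative_one(self, two_cluster_pattern):
        cur = nn_equality(two_cluster_pattern, "type", "a", "a", k_max=20,
                          cumulative=True, n_sim=9, seed=2)
        np.testing.assert_allclose(cur.observed, 1.0)

    def test_random_labels_not_flagged_by_global_test(self, unit_square):
        """Under random labelling the exact global rank test rejects at the
        nominal rate, so >= 90% of null curves pass at alpha = 0.05."""
        passed = 0
        for s in range(60):
            pp = syn.rpoispp(150, unit_square, 800 + s)
            pp = syn.label_random(pp, {"a": 0.5, "b": 0.5}, 900 + s)
            cur = nn_equality(pp, "type", "a", "b", k_max=8, n_sim=19, seed=1000 + s)
            if cur.p_value > 0.05:
                passed += 1
        assert passed / 60 >= 0.9
        # and the curve tracks the expected proportion on average
        assert abs(np.mean(cur.observed) - cur.theoretical[0]) < 0.25

    def test_k_max_too_large_rejected(self, two_cluster_pattern):
        with pytest.raises(ValueError):
            nn_equality(two_cluster_pattern, "type", "a", "b", k_max=120)
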