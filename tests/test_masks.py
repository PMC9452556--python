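"""Activation thresholds, overlap analytics, MANOVA and probability maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astrocircuit.masks import (
    ActivationMask,
    compare_bivariate,
    kmeans_threshold,
    make_mask,
    overlap_stats,
    pixel_correlation,
    probability_map,
)

from conftest import make_grid
from oracles import brute_force_kmeans_threshold


class TestKmeansThreshold:
    def test_two_well_separated_levels(self):
        vals = np.concatenate([np.zeros(900), np.full(100, 10.0)])
        rng = np.random.default_rng(0)
        vals += rng.normal(0, 1e-6, vals.size)  # break exact ties, keep separation
        g = make_grid(vals.reshape(20, 50))
        th = kmeans_threshold(g, 2)
        assert th == pytest.approx(10.0, abs=1e-3)
        assert (make_mask(g, th).mask.sum()) == 100

    def test_three_levels_with_k3(self):
        vals = np.repeat([0.0, 5.0, 10.0], [40, 40, 20]).astype(float)
        g = make_grid(vals.reshape(10, 10))
        th = kmeans_threshold(g, 3)
        assert th == 10.0
        assert make_mask(g, th).mask.sum() == 20

    def test_degenerate_input_is_an_error(self):
        g = make_grid(np.full((5, 5), 3.0))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_threshold(g, 2)

    def test_matches_exhaustive_partition_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(8, 15))
            if trial % 2:
                vals = rng.normal(0, 1, n)
            else:
                vals = np.concatenate(
                    [rng.normal(c, 0.2, n // 3 + 1) for c in (0, 3, 7)]
                )[:n]
            for k in (2, 3, 4):
                if np.unique(vals).size < k:
                    continue
                g = make_grid(vals.reshape(1, -1))
                assert kmeans_threshold(g, k) == pytest.approx(
                    brute_force_kmeans_threshold(vals, k)
                )

    def test_agrees_with_sklearn_on_well_separated_clusters(self):
        # independent library cross-check where the heuristic finds the optimum
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(c, 0.1, 60) for c in (0.0, 2.0, 4.0, 8.0)]
        )
        g = make_grid(vals.reshape(12, 20).copy())
        th = kmeans_threshold(g, 4)
        km = KMeans(n_clusters=4, n_init=25, random_state=0).fit(vals.reshape(-1, 1))
        top = np.argmax(km.cluster_centers_.ravel())
        assert th == pytest.approx(vals[km.labels_ == top].min())


class TestMakeMask:
    def test_threshold_at_minimum_activates_everything(self):
        g = make_grid(np.arange(9.0).reshape(3, 3))
        assert make_mask(g, 0.0).mask.all()

    def test_threshold_above_maximum_gives_empty_mask(self):
        g = make_grid(np.arange(9.0).reshape(3, 3))
        assert not make_mask(g, 99.0).mask.any()

    def test_value_exactly_at_threshold_is_active(self):
        g = make_grid(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert make_mask(g, 3.0).mask.sum() == 2  # cells 3 and 4

    def test_outside_nucleus_is_never_active(self):
        nucleus = np.array([[True, False], [True, True]])
        g = make_grid(np.full((2, 2), 5.0), nucleus=nucleus)
        m = make_mask(g, 0.0)
        assert not m.mask[0, 1]


def _mask(arr, **kw):
    return ActivationMask(mask=np.asarray(arr, bool), threshold=1.0, k=5, **kw)


class TestOverlapStats:
    def setup_method(self):
        self.nucleus = np.ones((10, 10), dtype=bool)

    def test_identical_masks_give_point_one_one(self):
        m = np.zeros((10, 10), bool)
        m[:3, :10] = True  # 30% of nucleus
        rep = overlap_stats(_mask(m), _mask(m), self.nucleus)["nucleus"]
        assert rep.overlap_pct == pytest.approx(30.0)
        assert (rep.bivariate_x, rep.bivariate_y) == (1.0, 1.0)

    def test_disjoint_masks_give_point_zero_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2] = True
        b[5:] = True
        rep = overlap_stats(_mask(a), _mask(b), self.nucleus)["nucleus"]
        assert rep.overlap_pct == 0.0
        assert (rep.bivariate_x, rep.bivariate_y) == (0.0, 0.0)

    def test_nested_masks(self):
        afferent = np.zeros((10, 10), bool)
        afferent[0, :10] = True  # 10 cells
        astro = np.zeros((10, 10), bool)
        astro[:4, :10] = True  # 40 cells, contains afferent
        rep = overlap_stats(_mask(afferent), _mask(astro), self.nucleus)["nucleus"]
        assert rep.overlap_pct == pytest.approx(10.0)
        assert rep.bivariate_x == pytest.approx(0.25)
        assert rep.bivariate_y == pytest.approx(1.0)

    def test_empty_denominator_is_reported_missing(self):
        empty = np.zeros((10, 10), bool)
        some = np.zeros((10, 10), bool)
        some[0] = True
        rep = overlap_stats(_mask(empty), _mask(some), self.nucleus)["nucleus"]
        assert rep.bivariate_y is None

    def test_subregion_reports(self):
        core = np.zeros((10, 10), bool)
        core[:5] = True
        shell = ~core
        a = np.zeros((10, 10), bool)
        a[:5] = True  # entirely in core
        rep = overlap_stats(_mask(a), _mask(a), self.nucleus, {"core": core, "shell": shell})
        assert rep["core"].overlap_pct == pytest.approx(100.0)
        assert rep["shell"].overlap_pct == 0.0

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            overlap_stats(
                _mask(np.zeros((2, 2), bool)), _mask(np.zeros((3, 3), bool)), np.ones((2, 2), bool)
            )

    @given(seed=st.integers(0, 300))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_overlap_bounds_and_bivariate_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8)) < 0.4
        b = rng.random((8, 8)) < 0.4
        rep = overlap_stats(_mask(a), _mask(b), np.ones((8, 8), bool))["nucleus"]
        assert rep.overlap_pct <= min(rep.afferent_pct, rep.astrocyte_pct) + 1e-12
        for v in (rep.bivariate_x, rep.bivariate_y):
            if v is not None:
                assert 0.0 <= v <= 1.0


class TestCompareBivariate:
    def test_identical_groups_are_indistinguishable(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.5, 0.1, (15, 2))
        rep = compare_bivariate(a, a.copy())
        assert rep.d == 0
        assert rep.p_value > 0.9

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.2, 0.05, (20, 2))
        b = rng.normal(0.8, 0.05, (20, 2))
        rep = compare_bivariate(a, b)
        assert rep.d == 1
        assert rep.p_value < 0.001

    def test_single_point_group_is_an_error(self):
        with pytest.raises(ValueError, match="2 points"):
            compare_bivariate(np.array([[0.1, 0.2]]), np.random.rand(5, 2))

    def test_degenerate_covariance_is_an_error(self):
        a = np.tile([0.5, 0.5], (6, 1))  # zero within-group scatter
        b = np.tile([0.6, 0.6], (6, 1))
        with pytest.raises(ValueError, match="degenerate"):
            compare_bivariate(a, b)

    def test_p_value_matches_statsmodels_manova(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(3)
        a = rng.normal(0.4, 0.12, (18, 2))
        b = rng.normal(0.55, 0.12, (14, 2))
        rep = compare_bivariate(a, b)
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        df["g"] = ["a"] * 18 + ["b"] * 14
        mv = MANOVA.from_formula("x + y ~ g", data=df)
        wilks_p = mv.mv_test().results["g"]["stat"].loc["Wilks' lambda", "Pr > F"]
        # chi-square (Bartlett) vs F approximations of the same Wilks statistic
        assert rep.p_value == pytest.approx(float(wilks_p), abs=0.02)


class TestPixelCorrelation:
    def test_identical_maps_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        g = make_grid(rng.normal(1, 0.3, (8, 8)))
        r, p = pixel_correlation(g, g)
        assert r == pytest.approx(1.0)

    def test_sign_flipped_map_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = make_grid(rng.normal(1, 0.3, (8, 8)))
        b = make_grid(-a.values + 5.0)
        r, _ = pixel_correlation(a, b)
        assert r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = make_grid(rng.normal(0, 1, (6, 6)))
        b = make_grid(rng.normal(0, 1, (6, 6)))
        r1, _ = pixel_correlation(a, b)
        r2, _ = pixel_correlation(b, a)
        assert r1 == pytest.approx(r2)
        scaled = make_grid(3.0 * b.values + 2.0)
        r3, _ = pixel_correlation(a, scaled)
        assert r3 == pytest.approx(r1)

    def test_thresholding_pairs_only_jointly_surviving_cells(self):
        vals_a = np.array([[1.0, 5.0, 6.0], [0.5, 5.5, 7.0], [0.2, 4.8, 6.5]])
        vals_b = vals_a[::-1].copy()
        a, b = make_grid(vals_a), make_grid(vals_b)
        r_all, _ = pixel_correlation(a, b)
        r_thr, _ = pixel_correlation(
            a, b, above_threshold_only=True, threshold_a=4.0, threshold_b=4.0
        )
        joint = (vals_a >= 4.0) & (vals_b >= 4.0)
        from scipy.stats import pearsonr

        expected = pearsonr(vals_a[joint], vals_b[joint])[0]
        assert r_thr == pytest.approx(expected)
        assert r_thr != pytest.approx(r_all)

    def test_too_few_cells_is_an_error(self):
        a = make_grid(np.ones((1, 2)))
        with pytest.raises(ValueError, match="3"):
            pixel_correlation(a, a)

    def test_independent_noise_maps_are_uncorrelated(self):
        rng = np.random.default_rng(4)
        low = 0
        for _ in range(100):
            a = make_grid(rng.normal(0, 1, (25, 40)))
            b = make_grid(rng.normal(0, 1, (25, 40)))
            r, _ = pixel_correlation(a, b)
            low += abs(r) < 0.1
        assert low >= 95


class TestProbabilityMap:
    def test_single_mask_is_identity(self):
        m = np.random.default_rng(0).random((5, 5)) < 0.5
        pm = probability_map([m])
        np.testing.assert_array_equal(pm.values, m.astype(float))

    def test_exact_rational_fractions(self):
        masks = [np.zeros((2, 2), bool) for _ in range(6)]
        for i in range(3):
            masks[i][0, 0] = True
        pm = probability_map(masks)
        assert pm.values[0, 0] == 0.5
        assert pm.n_slices == 6

    def test_all_empty_masks_give_zero_map(self):
        pm = probability_map([np.zeros((3, 3), bool)] * 4)
        np.testing.assert_array_equal(pm.values, 0.0)

    def test_identical_masks_reproduce_the_mask(self):
        m = np.random.default_rng(1).random((6, 6)) < 0.3
        pm = probability_map([m] * 7)
        np.testing.assert_array_equal(pm.values, m.astype(float))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            probability_map([])

    def test_values_always_within_unit_interval(self):
        rng = np.random.default_rng(2)
        masks = [rng.random((4, 4)) < rng.random() for _ in range(9)]
        pm = probability_map(masks)
        assert (pm.values >= 0).all() and (pm.values <= 1).all()


class TestMaskRecovery:
    def test_planted_blob_recovered_with_k6(self, analyzed_scene):
        scene, gt, basal, stim, afferent = analyzed_scene
        th = kmeans_threshold(stim, 6)
        m = make_mask(stim, th, k=6)
        inter = (m.mask & gt.planted_active_region).sum()
        union = (m.mask | gt.planted_active_region).sum()
        assert inter / union >= 0.8

    def test_afferent_blob_recovered_with_k5(self, analyzed_scene):
        scene, gt, basal, stim, afferent = analyzed_scene
        th = kmeans_threshold(afferent, 5)
        m = make_mask(afferent, th, k=5)
        inter = (m.mask & gt.planted_afferent_region).sum()
        union = (m.mask | gt.planted_afferent_region).sum()
        assert inter / union >= 0.8
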