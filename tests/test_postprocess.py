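"""Masking rules, decorrelated aggregation algebra, filters and summaries."""

import numpy as np
import pytest

from cloudshift.grids import AggregatedDeltaMap, DeltaMap, MaskReason, TopoStats, geo_axes
from cloudshift.postprocess import (CooccurrenceGrid, aggregate_blocks,
                                    block_presence, coarsen_for_display,
                                    cooccurrence_grid, cooccurrence_index,
                                    decorrelated_aggregate, filter_aggregates,
                                    mask_cooccurrence, mask_topography,
                                    merge_forest_types, relative_change,
                                    seasonal_positive_fraction,
                                    window_overlap_matrix)
from cloudshift.ingest import elevation_window_stats
from cloudshift.synthetic_world import (WorldConfig, generate_elevation)


def make_delta_map(n_months=12, n_trans=1, n=14, value=0.05, sigma=0.1):
    lat, lon = geo_axes(n, n, 0.05, 60.0, 10.0)
    shape = (n_months, n_trans, n, n)
    delta = np.full(shape, value)
    sig = np.full(shape, sigma)
    reason = np.zeros(shape, dtype=np.uint8)
    return DeltaMap(delta, sig, reason,
                    (("herbaceous", "deciduous_forest"),
                     ("herbaceous", "evergreen_forest"))[:n_trans],
                    lat, lon)


class TestCooccurrenceIndex:
    def test_ideal_line_configuration_scores_one(self):
        n = 49
        k = np.arange(n)
        p_a = (n - 1 - k) / (n - 1)
        p_b = k / (n - 1)
        assert cooccurrence_index(p_a, p_b) == pytest.approx(1.0)

    def test_joint_absence_matches_literal_formula(self):
        n = 49
        p_a = np.zeros(n)
        p_b = np.zeros(n)
        k = np.arange(n)
        q = np.column_stack([(n - 1 - k) / (n - 1), k / (n - 1)])
        num = np.hypot(q[:, 0], q[:, 1]).min() * n   # every p has the same min
        den = np.hypot(q[:, 0], q[:, 1]).sum()
        expected = max(0.0, 1.0 - num / den)
        got = cooccurrence_index(p_a, p_b)
        assert got == pytest.approx(expected)
        assert 0.0 < got < 0.5                        # small but nonzero

    def test_single_point_undefined(self):
        assert np.isnan(cooccurrence_index(np.array([0.5]), np.array([0.5])))


class TestMasking:
    def _cooc(self, delta_map, ic_value):
        ic = np.full(delta_map.delta.shape[2:], ic_value)
        return CooccurrenceGrid(ic, delta_map.transitions[0],
                                delta_map.lat, delta_map.lon)

    def test_full_cooccurrence_is_identity(self):
        dm = make_delta_map()
        out = mask_cooccurrence(dm, [self._cooc(dm, 1.0)])
        assert np.array_equal(out.delta, dm.delta)

    def test_zero_cooccurrence_masks_everything(self):
        dm = make_delta_map()
        out = mask_cooccurrence(dm, [self._cooc(dm, 0.0)])
        assert np.isnan(out.delta).all()
        assert (out.reason == MaskReason.COOCCURRENCE).all()

    def test_retention_boundary_is_inclusive_at_half(self):
        dm = make_delta_map(n_months=1)
        kept = mask_cooccurrence(dm, [self._cooc(dm, 0.50)])
        dropped = mask_cooccurrence(dm, [self._cooc(dm, 0.49)])
        assert np.isfinite(kept.delta).all()
        assert np.isnan(dropped.delta).all()

    def test_masked_count_matches_threshold_count(self):
        dm = make_delta_map(n_months=1)
        rng = np.random.default_rng(0)
        ic = rng.uniform(0, 1, dm.delta.shape[2:])
        grid = CooccurrenceGrid(ic, dm.transitions[0], dm.lat, dm.lon)
        out = mask_cooccurrence(dm, [grid])
        assert np.isnan(out.delta).sum() == (ic < 0.5).sum()

    def test_flat_terrain_topography_is_identity(self):
        dm = make_delta_map(n_months=1, n=15)
        topo = TopoStats(np.zeros((15, 15)), np.zeros((15, 15)),
                         np.zeros((15, 15)), dm.lat, dm.lon)
        out = mask_topography(dm, topo)
        assert np.array_equal(out.delta, dm.delta)

    def test_v1_at_sixty_metres_masked(self):
        dm = make_delta_map(n_months=1, n=14)
        v = np.zeros((14, 14))
        v1 = v.copy()
        v1[5, 5] = 60.0
        out = mask_topography(dm, TopoStats(v1, v, v, dm.lat, dm.lon))
        assert np.isnan(out.delta[0, 0, 5, 5])
        assert out.reason[0, 0, 5, 5] == MaskReason.TOPOGRAPHY
        assert np.isfinite(out.delta[0, 0, 6, 6])

    def test_ridge_mask_matches_direct_rule(self):
        cfg = WorldConfig(n_lat=21, n_lon=21, seed=0)
        topo = elevation_window_stats(generate_elevation(cfg, "ridge"))
        dm = make_delta_map(n_months=1, n=21)
        dm = DeltaMap(dm.delta, dm.sigma, dm.reason, dm.transitions,
                      topo.lat, topo.lon)
        out = mask_topography(dm, topo)
        rule = (topo.v1 < 50) & (topo.v2 < 100) & (topo.v3 < 100)
        assert np.array_equal(np.isfinite(out.delta[0, 0]), rule)

    def test_masking_is_idempotent_and_monotone(self):
        dm = make_delta_map(n_months=1)
        rng = np.random.default_rng(1)
        ic = rng.uniform(0, 1, dm.delta.shape[2:])
        grid = CooccurrenceGrid(ic, dm.transitions[0], dm.lat, dm.lon)
        once = mask_cooccurrence(dm, [grid])
        twice = mask_cooccurrence(once, [grid])
        assert np.array_equal(once.delta, twice.delta, equal_nan=True)
        assert np.isnan(twice.delta).sum() >= np.isnan(dm.delta).sum()


class TestOverlapMatrix:
    def test_same_center_full_overlap(self):
        R = window_overlap_matrix(np.array([3, 3]), np.array([4, 4]), 7)
        assert R[0, 1] == 1.0

    def test_one_column_apart_shares_six_sevenths(self):
        R = window_overlap_matrix(np.array([0, 0]), np.array([0, 1]), 7)
        assert R[0, 1] == pytest.approx(42 / 49)

    def test_disjoint_beyond_window_size(self):
        R = window_overlap_matrix(np.array([0, 0]), np.array([0, 7]), 7)
        assert R[0, 1] == 0.0

    def test_matches_explicit_pixel_set_intersection(self):
        rng = np.random.default_rng(2)
        rows = rng.integers(0, 10, 6)
        cols = rng.integers(0, 10, 6)
        R = window_overlap_matrix(rows, cols, 7)
        for i in range(6):
            for j in range(6):
                cells_i = {(r, c) for r in range(rows[i], rows[i] + 7)
                           for c in range(cols[i], cols[i] + 7)}
                cells_j = {(r, c) for r in range(rows[j], rows[j] + 7)
                           for c in range(cols[j], cols[j] + 7)}
                assert R[i, j] == pytest.approx(len(cells_i & cells_j) / 49)


class TestDecorrelatedAggregate:
    def test_independent_equal_sigma_reduces_to_plain_mean(self):
        deltas = np.array([0.01, 0.03, 0.05, 0.07])
        mean, var, w = decorrelated_aggregate(deltas, np.full(4, 0.1), np.eye(4))
        assert mean == pytest.approx(deltas.mean())
        assert np.allclose(w, 0.25)
        assert var == pytest.approx(0.01 / 4)

    def test_hand_computed_two_window_case(self):
        R = np.array([[1.0, 6 / 7], [6 / 7, 1.0]])
        mean, var, w = decorrelated_aggregate(np.array([0.04, 0.06]),
                                              np.array([0.1, 0.1]), R)
        assert mean == pytest.approx(0.05)
        assert var == pytest.approx(0.01 * (1 + 6 / 7) / 2)  # ~0.009286
        assert var == pytest.approx(0.009286, abs=1e-6)

    def test_single_center_passes_through(self):
        mean, var, w = decorrelated_aggregate(np.array([0.02]), np.array([0.3]),
                                              np.ones((1, 1)))
        assert mean == 0.02 and var == pytest.approx(0.09)

    def test_weights_sum_to_one_and_variance_identity(self):
        rng = np.random.default_rng(3)
        flat = rng.choice(49, size=12, replace=False)  # distinct centers
        rows, cols = np.divmod(flat, 7)
        R = window_overlap_matrix(rows, cols, 7)
        sig = rng.uniform(0.05, 0.3, 12)
        deltas = rng.normal(0.05, 0.02, 12)
        mean, var, w = decorrelated_aggregate(deltas, sig, R)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        cov = R * np.outer(sig, sig)
        assert w @ cov @ w == pytest.approx(var, abs=1e-9)
        assert 0 < var <= sig.max() ** 2 + 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            decorrelated_aggregate(np.array([]), np.array([]), np.empty((0, 0)))


class TestAggregateAndFilter:
    def test_constant_map_aggregates_to_constant(self):
        dm = make_delta_map(n_months=1, n=14, value=0.05)
        agg = aggregate_blocks(dm)
        assert agg.delta.shape[-2:] == (2, 2)
        assert np.allclose(agg.delta, 0.05)
        assert np.allclose(agg.support, 1.0)

    def test_low_support_block_removed(self):
        dm = make_delta_map(n_months=1, n=14)
        dm.delta[0, 0, :7, :7] = np.nan
        dm.delta[0, 0, 0, :5] = 0.05               # restore 9 of 49 centers
        dm.delta[0, 0, 1, :4] = 0.05               # -> support 18.4% < 20%
        agg = aggregate_blocks(dm)
        assert agg.support[0, 0, 0, 0] == pytest.approx(9 / 49)
        out = filter_aggregates(agg)
        assert np.isnan(out.delta[0, 0, 0, 0])
        assert np.isfinite(out.delta[0, 0, 1, 1])

    def test_high_variance_block_removed(self):
        dm = make_delta_map(n_months=1, n=14)
        agg = aggregate_blocks(dm)
        agg.variance[0, 0, 0, 0] = 0.11
        out = filter_aggregates(agg)
        assert np.isnan(out.delta[0, 0, 0, 0])

    def test_percentile_trim_matches_sort_based_oracle(self):
        rng = np.random.default_rng(4)
        n_m, nb = 12, 6
        delta = rng.normal(0.05, 0.02, (n_m, 1, nb, nb))
        var = np.full_like(delta, 1e-4)
        support = np.ones_like(delta)
        lat, lon = geo_axes(nb, nb, 0.35, 60.0, 10.0)
        agg = AggregatedDeltaMap(delta.copy(), var, support,
                                 (("herbaceous", "deciduous_forest"),), lat, lon)
        out = filter_aggregates(agg)
        lo, hi = np.percentile(delta, [1, 99])
        expected_removed = ((delta < lo) | (delta > hi)).sum()
        assert np.isnan(out.delta).sum() == expected_removed

    def test_empty_map_rejected(self):
        dm = make_delta_map(n_months=1, n=14)
        agg = aggregate_blocks(dm)
        agg.delta[:] = np.nan
        with pytest.raises(ValueError, match="empty"):
            filter_aggregates(agg)


class TestMergeRelativeCoarsen:
    def _agg(self, value, nb=3, n_trans=1):
        lat, lon = geo_axes(nb, nb, 0.35, 60.0, 10.0)
        shape = (12, n_trans, nb, nb)
        return AggregatedDeltaMap(np.full(shape, value, dtype=float),
                                  np.full(shape, 1e-4), np.ones(shape),
                                  (("herbaceous", "deciduous_forest"),), lat, lon)

    def test_equal_presence_is_arithmetic_mean(self):
        out = merge_forest_types(self._agg(0.02), self._agg(0.06),
                                 np.full((3, 3), 0.2), np.full((3, 3), 0.2))
        assert np.allclose(out.delta, 0.04)

    def test_absent_type_passes_other_through(self):
        out = merge_forest_types(self._agg(0.02), self._agg(0.06),
                                 np.full((3, 3), 0.3), np.zeros((3, 3)))
        assert np.allclose(out.delta, 0.02)

    def test_weighted_mean_hand_case(self):
        out = merge_forest_types(self._agg(0.02), self._agg(0.06),
                                 np.full((3, 3), 0.3), np.full((3, 3), 0.1))
        assert np.allclose(out.delta, 0.03)

    def test_negative_presence_rejected(self):
        with pytest.raises(ValueError):
            merge_forest_types(self._agg(0.02), self._agg(0.06),
                               np.full((3, 3), -0.1), np.full((3, 3), 0.1))

    def test_relative_change_is_elementwise_division(self):
        from cloudshift.grids import CloudGrid
        agg = self._agg(0.03)
        n = 3 * agg.block_size
        lat, lon = geo_axes(n, n, 0.05, 60.0, 10.0)
        clouds = CloudGrid(np.full((12, n, n), 0.6), lat, lon)
        rel = relative_change(agg, clouds)
        assert np.allclose(rel, 0.05)

    def test_relative_change_random_oracle(self):
        from cloudshift.grids import CloudGrid
        rng = np.random.default_rng(5)
        agg = self._agg(0.0)
        agg.delta[:] = rng.normal(0.03, 0.01, agg.delta.shape)
        n = 3 * agg.block_size
        lat, lon = geo_axes(n, n, 0.05, 60.0, 10.0)
        cl = rng.uniform(0.3, 0.9, (12, n, n))
        rel = relative_change(agg, CloudGrid(cl, lat, lon))
        block = cl.reshape(12, 3, 7, 3, 7).mean(axis=(2, 4))
        assert np.allclose(rel, agg.delta / block[:, None])

    def test_coarsen_preserves_constants_and_missing(self):
        vals = np.full((6, 6), 0.04)
        vals[:3, :3] = np.nan
        lat, lon = geo_axes(6, 6, 0.35, 60.0, 10.0)
        coarse, clat, clon = coarsen_for_display(vals, lat, lon, 3)
        assert np.isnan(coarse[0, 0])
        assert coarse[1, 1] == pytest.approx(0.04)

    def test_coarsen_matches_block_mean_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, (9, 9))
        lat, lon = geo_axes(9, 9, 0.35, 60.0, 10.0)
        coarse, _, _ = coarsen_for_display(vals, lat, lon, 3)
        for i in range(3):
            for j in range(3):
                assert coarse[i, j] == pytest.approx(
                    vals[i * 3:(i + 1) * 3, j * 3:(j + 1) * 3].mean())


class TestSeasonalSummary:
    def _agg(self, delta):
        nb = delta.shape[-1]
        lat, lon = geo_axes(nb, nb, 0.35, 60.0, 10.0)
        return AggregatedDeltaMap(delta, np.full_like(delta, 1e-4),
                                  np.ones_like(delta),
                                  (("herbaceous", "forest"),), lat, lon)

    def test_all_positive_map_scores_hundred_percent(self):
        agg = self._agg(np.full((12, 1, 4, 4), 0.02))
        out = seasonal_positive_fraction(agg)
        assert np.allclose(out[out.month > 0]["pct_positive"], 100.0)
        assert out[out.month == 0]["pct_positive"].iloc[0] == pytest.approx(100.0)

    def test_southern_hemisphere_cycled_six_months(self):
        delta = np.full((12, 1, 2, 2), np.nan)
        delta[0] = 0.02                            # January only
        agg = self._agg(delta)
        agg.lat = np.array([-10.0, -10.5])         # all blocks southern
        out = seasonal_positive_fraction(agg)
        by_month = out.set_index("month")
        assert by_month.loc[7, "n_cells"] == 4     # counted in July bin
        assert by_month.loc[1, "n_cells"] == 0

    def test_mixed_map_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        delta = rng.normal(0.0, 1.0, (12, 1, 5, 5))
        agg = self._agg(delta)
        out = seasonal_positive_fraction(agg)
        for m in (1, 5, 12):
            vals = delta[m - 1, 0].ravel()
            expected = 100.0 * (vals > 0).sum() / vals.size
            assert out.set_index("month").loc[m, "pct_positive"] == pytest.approx(expected)

    def test_positive_plus_negative_is_hundred(self):
        rng = np.random.default_rng(8)
        agg = self._agg(rng.normal(0, 1, (12, 1, 4, 4)))
        out = seasonal_positive_fraction(agg)
        months = out[out.month > 0]
        assert np.allclose(months.pct_positive + months.pct_negative, 100.0)


def test_block_presence_is_blockwise_mean(small_world):
    fractions, _, _ = small_world
    pres = block_presence(fractions, "deciduous_forest", 7)
    layer = fractions.layer("deciduous_forest")
    assert pres[0, 0] == pytest.approx(layer[:7, :7].mean())
    assert pres.shape == (8, 8)


def test_cooccurrence_grid_matches_per_window_index(small_world):
    fractions, _, _ = small_world
    grid = cooccurrence_grid(fractions, "herbaceous", "deciduous_forest")
    a = fractions.layer("herbaceous")
    b = fractions.layer("deciduous_forest")
    w = fractions.layer("water")
    for r, c in [(10, 10), (25, 40)]:
        sl = (slice(r - 3, r + 4), slice(c - 3, c + 4))
        ok = (w[sl] < 0.5).ravel()
        expected = cooccurrence_index(a[sl].ravel()[ok], b[sl].ravel()[ok])
        assert grid.ic[r, c] == pytest.approx(expected)
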