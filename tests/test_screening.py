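"""Pearson screening, best-index selection and heat-map summation."""

import numpy as np
import pytest

import hyperleaf as hl
from hyperleaf.grid import SpectralGrid
from hyperleaf.indices import IndexDescriptor, default_registry, enumerate_indices, evaluate_all
from hyperleaf.screening import (
    CorrelationResult,
    HeatMatrix,
    best_index,
    correlate_all,
    pearson_r,
    screen_exhaustive,
    summed_heatmap,
)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r(np.array([1.0, 2, 3, 4]), np.array([2.0, 1, 4, 3])) == pytest.approx(0.6)

    def test_zero_variance_flagged_as_nan(self):
        assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))

    def test_affine_invariance_property(self):
        rng = np.random.default_rng(21)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r = pearson_r(x, y)
        assert pearson_r(3.2 * x + 7, y) == pytest.approx(r)
        assert pearson_r(-2.0 * x, y) == pytest.approx(-r)

    def test_log_base_does_not_change_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.1, 0.9, 40)
        y = rng.normal(size=40)
        assert pearson_r(np.log10(x), y) == pytest.approx(pearson_r(np.log(x), y))


class TestCorrelateAll:
    def test_matches_per_column_pearson(self, toy_grid):
        rng = np.random.default_rng(8)
        spectra = rng.uniform(0.05, 0.9, (25, 2))
        table = evaluate_all(spectra, toy_grid)
        y = rng.normal(size=25)
        res = correlate_all(table, {"y": y})["y"]
        brute = np.array([pearson_r(table.values[:, k], y) for k in range(table.values.shape[1])])
        np.testing.assert_allclose(res.r, brute, atol=1e-10, equal_nan=True)

    def test_column_equal_to_target_ranks_first(self, toy_grid):
        rng = np.random.default_rng(9)
        spectra = rng.uniform(0.05, 0.9, (20, 2))
        table = evaluate_all(spectra, toy_grid)
        y = table.values[:, 5].copy()
        res = correlate_all(table, {"y": y})["y"]
        assert res.r[5] == pytest.approx(1.0)
        # a perfectly anticorrelated twin column may tie on |r|
        assert abs(res.r[res.ranking()[0]]) == pytest.approx(1.0)

    def test_misaligned_target_rejected_by_name(self, toy_grid):
        table = evaluate_all(np.full((4, 2), 0.5), toy_grid)
        with pytest.raises(ValueError, match="bad_target"):
            correlate_all(table, {"bad_target": np.zeros(3)})


class TestBestIndex:
    def test_single_candidate_is_returned(self):
        d = IndexDescriptor("original", "R", 0)
        res = CorrelationResult("y", np.array([0.7]), 10, [d])
        assert best_index(res) == (d, 0.7)

    def test_absolute_value_ranking_keeps_sign(self):
        ds = [IndexDescriptor("original", "R", 0), IndexDescriptor("original", "R", 1)]
        res = CorrelationResult("y", np.array([0.9, -0.95]), 10, ds)
        winner, r = best_index(res)
        assert winner == ds[1] and r == -0.95

    def test_all_flagged_rejected(self):
        res = CorrelationResult("y", np.array([np.nan, np.nan]), 10,
                                [IndexDescriptor("original", "R", 0), IndexDescriptor("original", "R", 1)])
        with pytest.raises(ValueError):
            best_index(res)

    def test_restriction_is_set_inclusion(self, dataset150):
        from hyperleaf.indices import primary_subset

        spectra, pigments = dataset150
        grid = hl.SpectralGrid.default()
        y = pigments["Ca"].to_numpy()
        descriptors = enumerate_indices(grid)
        table_r = screen_exhaustive(spectra, y, grid)
        table_r.descriptors = descriptors
        unrestricted, _ = best_index(table_r)
        subset = primary_subset(descriptors, grid)
        restricted, _ = best_index(table_r, restrict=subset)
        assert restricted in set(subset)
        if unrestricted in set(subset):
            assert restricted == unrestricted


class TestScreenExhaustive:
    def test_equals_table_route_on_small_grid(self):
        grid = SpectralGrid(np.linspace(450, 950, 6))
        registry = default_registry(3, 4)
        rng = np.random.default_rng(1)
        spectra = rng.uniform(0.05, 0.9, (20, 6))
        y = rng.normal(size=20)
        r_stream = screen_exhaustive(spectra, y, grid, registry).r
        table = evaluate_all(spectra, grid, registry=registry)
        r_table = correlate_all(table, {"y": y})["y"].r
        np.testing.assert_allclose(r_stream, r_table, atol=1e-12, equal_nan=True)

    def test_winner_descriptor_reconstruction(self, dataset150):
        spectra, pigments = dataset150
        grid = hl.SpectralGrid.default()
        res = screen_exhaustive(spectra, pigments["Ca"].to_numpy(), grid)
        winner, r = best_index(res)
        # cross-check the reconstructed descriptor's own correlation
        x = evaluate_all(spectra, grid, descriptors=[winner]).values[:, 0]
        assert pearson_r(x, pigments["Ca"].to_numpy()) == pytest.approx(r, abs=1e-10)


class TestHeatmaps:
    def test_single_matrix_sum_is_absolute_value(self):
        vals = np.array([[np.nan, -0.5], [0.25, np.nan]])
        hm = HeatMatrix("ratio", "R", "Ca", vals)
        total = summed_heatmap([hm])
        assert total[0, 1] == pytest.approx(0.5)
        assert total[1, 0] == pytest.approx(0.25)
        assert np.isnan(total[0, 0])

    def test_k_copies_scale_linearly(self):
        vals = np.array([[np.nan, -0.5], [0.25, np.nan]])
        hm = HeatMatrix("ratio", "R", "Ca", vals)
        total = summed_heatmap([hm] * 4)
        assert total[0, 1] == pytest.approx(2.0)

    def test_grid_mismatch_rejected(self):
        a = HeatMatrix("ratio", "R", "Ca", np.zeros((2, 2)))
        b = HeatMatrix("ratio", "R", "Ca", np.zeros((3, 3)))
        with pytest.raises(ValueError):
            summed_heatmap([a, b])

    def test_hot_region_localizes_informative_bands(self, dataset150):
        spectra, pigments = dataset150
        grid = hl.SpectralGrid.default()
        _, maps = screen_exhaustive(
            spectra[:60], pigments["Ca"].to_numpy()[:60], grid, return_heatmaps=True
        )
        assert len(maps) == 18
        total = summed_heatmap(maps)
        i, j = np.unravel_index(np.nanargmax(total), total.shape)
        wl = sorted([grid.centers[i], grid.centers[j]])
        # the generative model makes the pigment-absorption/red-edge region
        # informative; at least one band of the argmax pair sits on the red edge
        assert 450 <= wl[0] <= 800 and 450 <= wl[1] <= 800
        assert any(660 <= w <= 760 for w in wl)
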