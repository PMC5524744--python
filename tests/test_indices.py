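"""Index enumeration census, transform evaluation and the primary subset."""

import numpy as np
import pytest

import hyperleaf as hl
from hyperleaf.grid import SpectralGrid
from hyperleaf.indices import (
    IndexDescriptor,
    census,
    default_registry,
    descriptor_at,
    enumerate_indices,
    evaluate_all,
    evaluate_index,
    primary_census,
    primary_subset,
    spectrum_from_roi,
)


class TestCensus:
    def test_instrument_grid_with_default_registry(self):
        c = census(188, 20, 95)
        assert c["total"] == 634_615
        assert c["pseudo_absorption"] == 376
        assert c["first_derivative"] == 564
        assert c["second_derivative"] == 564
        assert c["ratio"] == 316_404
        assert c["normalized"] == 316_404

    def test_two_band_grid_empty_registry(self, toy_grid):
        assert len(enumerate_indices(toy_grid)) == 54
        assert census(2)["total"] == 54

    def test_single_band_grid_has_no_pair_indices(self):
        grid = SpectralGrid(np.array([600.0]))
        descs = enumerate_indices(grid)
        assert len(descs) == 9
        assert all(d.j is None for d in descs)

    @pytest.mark.parametrize("n", [2, 3, 5, 11])
    def test_census_formula_matches_enumeration(self, n):
        grid = SpectralGrid(np.linspace(450, 950, n))
        assert len(enumerate_indices(grid)) == 9 * n + 18 * n * (n - 1)

    def test_enumeration_matches_positional_reconstruction(self):
        grid = SpectralGrid(np.linspace(450, 950, 5))
        registry = default_registry(3, 4)
        descs = enumerate_indices(grid, registry)
        for k in range(len(descs)):
            assert descriptor_at(k, grid, registry) == descs[k]


class TestRegistry:
    def test_default_counts(self):
        reg = default_registry()
        assert reg.counts == (20, 95)

    def test_labels_unique(self):
        reg = default_registry()
        labels = [e.label for e in reg.position + reg.published]
        assert len(labels) == len(set(labels))

    def test_red_edge_position_on_synthetic_spectrum(self, grid):
        from hyperleaf.synthetic import leaf_spectrum

        reg = default_registry()
        spectrum = leaf_spectrum(300.0, 100.0, 60.0, grid)
        rep = reg.lookup("REP_maxdR").fn(spectrum, grid)
        assert 680 <= rep <= 760


class TestEvaluateIndex:
    def test_constant_spectrum_symmetries(self):
        grid = SpectralGrid(np.linspace(450, 950, 6))
        spectrum = np.full(6, 0.3)
        derivative_transforms = ("dR", "dlgR", "dlg1R", "ddR", "ddlgR", "ddlg1R")
        for d in enumerate_indices(grid):
            v = evaluate_index(spectrum, d, grid)
            if d.family in ("first_derivative", "second_derivative"):
                assert v == pytest.approx(0.0, abs=1e-12)
            elif d.family in ("ratio", "normalized") and d.transform in derivative_transforms:
                # 0/0 on a flat spectrum: guarded and flagged, not silent
                assert np.isnan(v)
            elif d.family == "ratio":
                assert v == pytest.approx(1.0)
            elif d.family == "normalized":
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_log_ratio_with_exact_powers_of_ten(self):
        grid = SpectralGrid(np.array([500.0, 715.0]))
        spectrum = np.array([0.01, 0.1])  # lg = -2, -1
        d = IndexDescriptor("ratio", "lgR", i=1, j=0)
        assert evaluate_index(spectrum, d, grid) == pytest.approx(0.5)

    def test_first_derivative_exact_on_affine_spectrum(self):
        grid = SpectralGrid(np.linspace(400, 1000, 25))
        b = 1e-4
        spectrum = 0.05 + b * grid.centers
        for i in range(1, 24):
            v = evaluate_index(spectrum, IndexDescriptor("first_derivative", "dR", i), grid)
            assert v == pytest.approx(b, rel=1e-9)

    def test_guarded_ratio_denominator_flags_nan(self):
        grid = SpectralGrid(np.linspace(400, 1000, 4))
        spectrum = 0.05 + 1e-4 * grid.centers  # constant dR -> ddR == 0
        d = IndexDescriptor("ratio", "ddR", i=1, j=2)
        assert np.isnan(evaluate_index(spectrum, d, grid))


class TestEvaluateAll:
    def test_matches_per_index_evaluation_with_registry(self):
        grid = SpectralGrid(np.linspace(450, 950, 3))
        registry = default_registry(3, 4)
        rng = np.random.default_rng(7)
        spectra = rng.uniform(0.05, 0.9, (8, 3))
        table = evaluate_all(spectra, grid, registry=registry)
        descs = enumerate_indices(grid, registry)
        assert table.descriptors == descs
        brute = np.array(
            [[evaluate_index(s, d, grid, registry) for d in descs] for s in spectra]
        )
        np.testing.assert_allclose(table.values, brute, equal_nan=True)

    def test_row_permutation_permutes_rows_only(self, toy_grid):
        rng = np.random.default_rng(3)
        spectra = rng.uniform(0.1, 0.9, (6, 2))
        perm = rng.permutation(6)
        a = evaluate_all(spectra, toy_grid).values
        b = evaluate_all(spectra[perm], toy_grid).values
        np.testing.assert_allclose(b, a[perm], equal_nan=True)

    def test_ratio_reciprocal_identity_and_normalized_antisymmetry(self):
        grid = SpectralGrid(np.linspace(450, 950, 4))
        rng = np.random.default_rng(11)
        spectra = rng.uniform(0.1, 0.9, (5, 4))
        table = evaluate_all(spectra, grid)
        vals = {d: table.values[:, k] for k, d in enumerate(table.descriptors)}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rij = vals[IndexDescriptor("ratio", "R", i, j)]
                rji = vals[IndexDescriptor("ratio", "R", j, i)]
                np.testing.assert_allclose(rij * rji, 1.0)
                nij = vals[IndexDescriptor("normalized", "R", i, j)]
                nji = vals[IndexDescriptor("normalized", "R", j, i)]
                np.testing.assert_allclose(nij, -nji, atol=1e-12)
                assert np.all(np.abs(nij) <= 1.0 + 1e-12)


class TestSpectrumFromROI:
    def test_two_pixel_mean(self, toy_grid):
        data = np.zeros((2, 2, 1))
        data[:, 0, 0] = [0.2, 0.6]
        data[:, 1, 0] = [0.4, 0.8]
        cube = hl.HyperCube(data=data, grid=toy_grid, state="reflectance")
        mask = np.ones((2, 1), dtype=bool)
        np.testing.assert_allclose(spectrum_from_roi(cube, mask), [0.3, 0.7])

    def test_empty_mask_rejected(self, toy_grid):
        cube = hl.HyperCube(np.full((2, 3, 3), 0.5), toy_grid, state="reflectance")
        with pytest.raises(ValueError, match="empty"):
            spectrum_from_roi(cube, np.zeros((3, 3), dtype=bool))

    def test_leaf_mean_close_to_noiseless_model(self, scene42):
        from hyperleaf.synthetic import leaf_spectrum

        cube, truth = scene42
        mask = truth.masks[0]
        mean = spectrum_from_roi(cube, mask)
        # compare to the noiseless generative spectrum averaged over the
        # leaf's pigment raster
        model = np.mean(
            [
                leaf_spectrum(ca, cb, cx, cube.grid)
                for ca, cb, cx in zip(
                    truth.ca_raster[mask][::50],
                    truth.cb_raster[mask][::50],
                    truth.cxc_raster[mask][::50],
                )
            ],
            axis=0,
        )
        noise_of_mean = 3 * 0.005 / np.sqrt(mask.sum() / 50)
        assert np.max(np.abs(mean - model)) < max(0.01, noise_of_mean * 5)


class TestPrimarySubset:
    def test_window_with_no_bands_is_empty(self, grid):
        assert primary_subset(enumerate_indices(grid), grid, (1100.0, 1200.0)) == []

    def test_three_band_window_hand_count(self):
        grid = SpectralGrid(np.array([600.0, 710.0, 730.0, 750.0, 900.0]))
        sub = primary_subset(enumerate_indices(grid), grid, (700.0, 760.0))
        # m = 3 window bands: 3m singles + m(m-1) unordered pair indices = 15
        assert len(sub) == 15
        assert len(sub) == primary_census(3)

    def test_21_band_window_gives_483(self):
        centers = np.concatenate(
            [np.linspace(400, 690, 40), np.linspace(700, 760, 21), np.linspace(775, 1000, 30)]
        )
        grid = SpectralGrid(centers)
        sub = primary_subset(enumerate_indices(grid), grid)
        assert len(sub) == 483

    def test_subset_families_and_bands(self, grid):
        sub = primary_subset(enumerate_indices(grid), grid)
        lo, hi = 700.0, 760.0
        for d in sub:
            assert lo <= grid.centers[d.i] <= hi
            if d.j is not None:
                assert lo <= grid.centers[d.j] <= hi
                assert d.i < d.j
                assert d.transform == "R"
            else:
                assert d.transform in ("R", "dR", "ddR")
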