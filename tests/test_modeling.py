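"""Model forms, metrics, cross-validation and stepwise regression."""

import numpy as np
import pytest

from hyperleaf.modeling import (
    PUBLISHED_MODELS,
    fit_form,
    kfold_cv,
    model_metrics,
    stepwise_regression,
)
from hyperleaf.screening import pearson_r


class TestFitForm:
    def test_noiseless_linear_recovery(self):
        x = np.linspace(0.5, 3.0, 20)
        m = fit_form(x, 3 * x + 2, "linear")
        assert m.coefficients == pytest.approx((2.0, 3.0))
        assert m.metrics.r2 == pytest.approx(1.0)
        assert m.metrics.mape == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_power_recovery(self):
        x = np.linspace(0.5, 3.0, 20)
        m = fit_form(x, 2 * x**1.5, "power")
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert m.coefficients[1] == pytest.approx(1.5, abs=1e-8)

    def test_noiseless_exponential_recovery(self):
        x = np.linspace(0.0, 2.0, 20)
        m = fit_form(x, 1.7 * np.exp(0.8 * x), "exponential")
        assert m.coefficients == pytest.approx((1.7, 0.8), abs=1e-8)

    def test_noiseless_logarithmic_recovery(self):
        x = np.linspace(0.5, 4.0, 20)
        m = fit_form(x, 5.0 * np.log(2.0 * x), "logarithmic")
        assert m.coefficients == pytest.approx((5.0, 2.0), abs=1e-8)
        np.testing.assert_allclose(m.predict(x), 5.0 * np.log(2.0 * x), atol=1e-8)

    def test_noiseless_quadratic_recovery(self):
        x = np.linspace(-2.0, 2.0, 20)
        m = fit_form(x, 1.0 - 2.0 * x + 0.5 * x**2, "quadratic")
        assert m.coefficients == pytest.approx((1.0, -2.0, 0.5))

    def test_power_rejects_nonpositive_domain(self):
        x = np.linspace(-1.0, 1.0, 10)
        with pytest.raises(ValueError):
            fit_form(x, np.abs(x) + 1, "power")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_form(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "quadratic")

    def test_linear_r2_equals_squared_pearson(self, dataset150):
        spectra, pigments = dataset150
        x = spectra[:, 100]
        y = pigments["Ca"].to_numpy()
        m = fit_form(x, y, "linear")
        assert m.metrics.r2 == pytest.approx(pearson_r(x, y) ** 2, abs=1e-10)

    def test_synthetic_index_fit_reaches_high_r2(self, dataset150):
        spectra, pigments = dataset150
        grid_band_715 = 99  # band nearest 717.6 nm on the default grid
        x = np.log10(np.clip(spectra[:, grid_band_715], 1e-6, None))
        m = fit_form(x, pigments["Ca"].to_numpy(), "linear")
        assert m.metrics.r2 >= 0.9

    def test_parameter_recovery_within_three_se(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(77)
        hits = 0
        reps = 60
        for _ in range(reps):
            x = rng.uniform(0, 1, 80)
            y = 10.0 + 4.0 * x + rng.normal(0, 0.5, 80)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            ok = abs(fit.params[0] - 10.0) < 3 * fit.bse[0] and abs(fit.params[1] - 4.0) < 3 * fit.bse[1]
            hits += ok
        assert hits / reps >= 0.95


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([10.0, 20.0, 30.0])
        assert model_metrics(y, y) == pytest.approx((1.0, 0.0, 0.0, 0.0))

    def test_hand_computed_example(self):
        m = model_metrics(np.array([100.0, 200.0]), np.array([110.0, 180.0]))
        assert m.mape == pytest.approx(10.0)
        assert m.rmse == pytest.approx(np.sqrt(250.0))
        # APEs are 10% and 10%; sample sd of equal values is 0
        assert m.sd_ape == pytest.approx(0.0)

    def test_sd_ape_uses_sample_denominator(self):
        m = model_metrics(np.array([100.0, 100.0]), np.array([110.0, 130.0]))
        # APEs 10 and 30 -> sample sd = sqrt(((10-20)^2+(30-20)^2)/1)
        assert m.sd_ape == pytest.approx(np.sqrt(200.0))

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = model_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_zero_observations_excluded_from_percentage_errors(self):
        m = model_metrics(np.array([0.0, 100.0]), np.array([5.0, 110.0]))
        assert m.mape == pytest.approx(10.0)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(50, 500, 30)
        yhat = y + rng.normal(0, 10, 30)
        perm = rng.permutation(30)
        assert model_metrics(y, yhat) == pytest.approx(model_metrics(y[perm], yhat[perm]))


class TestKFoldCV:
    def test_noiseless_linear_validates_perfectly(self):
        x = np.linspace(1, 10, 40)
        report = kfold_cv(x, 2 * x + 5, "linear", k=5, seed=0)
        for fold in report.fold_validation:
            assert fold.mape == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 50)
        y = 3 * x + rng.normal(0, 0.1, 50)
        a = kfold_cv(x, y, "linear", seed=42)
        b = kfold_cv(x, y, "linear", seed=42)
        assert a.fold_validation == b.fold_validation

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_cv(np.arange(3.0), np.arange(3.0), "linear", k=5)

    def test_validation_tracks_modeling_on_well_specified_data(self, dataset150):
        spectra, pigments = dataset150
        x = np.log10(np.clip(spectra[:, 99], 1e-6, None))
        y = pigments["Ca"].to_numpy()
        report = kfold_cv(x, y, "linear", k=5, seed=0)
        rm, rv = report.mean_modeling.rmse, report.mean_validation.rmse
        assert rv <= rm * 1.25


class TestStepwise:
    def test_single_perfect_candidate_selected(self):
        x = np.linspace(0, 1, 30)
        model = stepwise_regression(x[:, None], 4 * x + 1, names=["x0"])
        assert model.selected == ["x0"]
        assert model.r2 == pytest.approx(1.0)

    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 10))
        y = rng.normal(size=60)
        model = stepwise_regression(X, y, entry_p=0.01)
        assert model.selected == []
        assert model.note is not None

    def test_true_support_recovered_among_decoys(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(120, 20))
        y = 2.0 * X[:, 3] - 1.5 * X[:, 11] + rng.normal(0, 0.1, 120)
        model = stepwise_regression(X, y)
        assert {"x3", "x11"}.issubset(set(model.selected))
        assert model.coefficients["x3"] == pytest.approx(2.0, abs=0.1)
        assert model.r2 > 0.99

    def test_entering_variables_never_decreases_r2(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(19)
        X = rng.normal(size=(80, 5))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 80)
        model = stepwise_regression(X, y)
        r2_prev = 0.0
        cols: list[int] = []
        names = [f"x{k}" for k in range(5)]
        for action, name, _ in model.trace:
            if action != "enter":
                continue
            cols.append(names.index(name))
            r2 = sm.OLS(y, sm.add_constant(X[:, cols])).fit().rsquared
            assert r2 >= r2_prev - 1e-12
            r2_prev = r2


class TestPresets:
    def test_eight_presets_ship(self):
        assert len(PUBLISHED_MODELS) == 8
        stages = {p.stage for p in PUBLISHED_MODELS}
        assert stages == {"tillering", "heading"}

    def test_tillering_chla_prediction_at_unit_index(self):
        preset = PUBLISHED_MODELS[0]
        assert preset.pigment == "Ca"
        assert preset.predict(1.0) == pytest.approx(916.642)

    def test_preset_descriptor_resolves_on_instrument_grid(self, grid):
        d = PUBLISHED_MODELS[0].descriptor(grid)
        assert d.family == "ratio" and d.transform == "lgR"
        assert abs(grid.centers[d.i] - 715) <= 2
        assert abs(grid.centers[d.j] - 500) <= 2
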