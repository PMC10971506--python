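import numpy as np
import pandas as pd
import pytest

from ebullition.models import (AdditiveModel, ModelSpec, binned_response_model,
                               evaluate_model, fit_gam, load_registry,
                               predict_literature_model, refit_model)


def brute_force_metrics(o, p):
    """Loop-based reference implementation of the evaluation metrics."""
    n = len(o)
    om = sum(o) / n
    pm = sum(p) / n
    sxy = sxx = syy = sse = 0.0
    for oi, pi in zip(o, p):
        sxy += (pi - pm) * (oi - om)
        sxx += (pi - pm) ** 2
        syy += (oi - om) ** 2
        sse += (oi - pi) ** 2
    r2 = (sxy * sxy) / (sxx * syy)
    rmse = (sse / n) ** 0.5
    nse = 1.0 - sse / syy
    rel = 100.0 * (sum(o) - sum(p)) / sum(o)
    return r2, rmse, nse, rel


class TestEvaluateModel:
    def test_perfect_prediction(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate_model(o, o.copy())
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.nse == pytest.approx(1.0)
        assert rep.rel_error_pct == pytest.approx(0.0)

    def test_mean_forecast_has_zero_nse(self):
        rng = np.random.default_rng(0)
        o = rng.exponential(5, 100)
        rep = evaluate_model(o, np.full_like(o, o.mean()))
        assert rep.nse == pytest.approx(0.0, abs=1e-12)
        assert rep.r2 == 0.0  # constant prediction: no linear information

    def test_doubling_gives_minus_hundred_percent(self):
        o = np.array([1.0, 0.0, 3.0, 2.0])
        rep = evaluate_model(o, 2 * o)
        assert rep.rel_error_pct == pytest.approx(-100.0)  # overestimation

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            o = rng.normal(10, 3, 20)
            p = o + rng.normal(0, 1, 20)
            rep = evaluate_model(o, p)
            r2, rmse, nse, rel = brute_force_metrics(o.tolist(), p.tolist())
            assert rep.r2 == pytest.approx(r2, abs=1e-10)
            assert rep.rmse == pytest.approx(rmse, abs=1e-10)
            assert rep.nse == pytest.approx(nse, abs=1e-10)
            assert rep.rel_error_pct == pytest.approx(rel, abs=1e-10)

    def test_accumulation_windows_restrict_relative_error(self):
        idx = pd.date_range("2019-01-01", periods=10, freq="1d")
        o = np.ones(10)
        p = np.ones(10)
        p[:5] = 2.0  # overestimates only in the first window
        rep = evaluate_model(o, p, accumulation_windows=[("2019-01-06", "2019-01-10")],
                             index=idx)
        assert rep.rel_error_pct == pytest.approx(0.0)

    def test_zero_accumulated_flux_undefined(self):
        idx = pd.date_range("2019-01-01", periods=5, freq="1d")
        rep = evaluate_model(np.zeros(5), np.ones(5), index=idx)
        assert rep.rel_error_pct is None


class TestBinnedResponse:
    def test_constant_flux_flat_model(self):
        rng = np.random.default_rng(0)
        temp = rng.uniform(16, 23, 500)
        model = binned_response_model(np.full(500, 7.5), temp)
        np.testing.assert_allclose(model.bin_means, 7.5)
        np.testing.assert_allclose(model.predict(np.linspace(17, 22, 5)), 7.5, atol=1e-8)

    def test_exact_cubic_recovered(self):
        temp = np.repeat(np.arange(15.5, 24.5), 20)  # bin centers hit exactly
        coeffs = np.array([0.02, -1.0, 17.0, -80.0])
        flux = np.polyval(coeffs, temp)
        model = binned_response_model(flux, temp, bin_width=1.0, degree=3)
        np.testing.assert_allclose(model.poly_coeffs, coeffs, atol=1e-8)

    def test_percentile_bars_bracket_mean(self):
        rng = np.random.default_rng(2)
        temp = rng.uniform(16, 23, 2000)
        flux = rng.exponential(20, 2000) * (temp > 18)
        model = binned_response_model(flux, temp)
        assert (model.p10 <= model.bin_means + 1e-9).all()
        assert (model.bin_means <= model.p90 + 1e-9).all()

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="3 non-empty bins"):
            binned_response_model(np.ones(50), np.full(50, 20.0))


class TestLiteratureForms:
    def test_pressure_above_threshold_predicts_zero(self):
        spec = ModelSpec(name="thr", form="pressure_threshold", timescale="1d",
                         predictors=["total_pressure"],
                         coefficients={"rate_constant": 5.0, "pressure_threshold": 200.0})
        table = pd.DataFrame({"total_pressure": [205.0, 210.0, 230.0]})
        np.testing.assert_allclose(predict_literature_model(spec, table), 0.0)

    def test_autoregressive_zero_slopes_constant(self):
        spec = ModelSpec(name="ar", form="autoregressive", timescale="1w",
                         predictors=["flux_lag1", "temp_bottom"],
                         coefficients={"intercept": 4.2, "flux_lag1": 0.0,
                                       "temp_bottom": 0.0})
        table = pd.DataFrame({"flux_lag1": [1.0, 9.0], "temp_bottom": [16.0, 23.0]})
        np.testing.assert_allclose(predict_literature_model(spec, table), 4.2)

    def test_arrhenius_reference_temperature_identity(self):
        spec = ModelSpec(name="arr", form="arrhenius", timescale="1d",
                         predictors=["temp_bottom"],
                         coefficients={"flux_at_20C": 33.0, "theta": 0.25})
        table = pd.DataFrame({"temp_bottom": [20.0]})
        assert predict_literature_model(spec, table)[0] == pytest.approx(33.0)

    def test_missing_predictor_named_in_error(self):
        spec = ModelSpec(name="lin", form="linear", timescale="1d",
                         predictors=["wind_speed"], coefficients={"intercept": 0.0,
                                                                  "wind_speed": 1.0})
        with pytest.raises(KeyError, match="wind_speed"):
            predict_literature_model(spec, pd.DataFrame({"temp": [1.0]}))

    def test_missing_coefficient_rejected(self):
        spec = ModelSpec(name="lin", form="linear", timescale="1d",
                         predictors=["x"], coefficients={"intercept": 1.0})
        with pytest.raises(ValueError, match="coefficient"):
            predict_literature_model(spec, pd.DataFrame({"x": [1.0]}))

    def test_registry_ships_eight_refittable_forms(self):
        specs = load_registry()
        assert len(specs) == 8
        assert all(not s.is_fixed for s in specs)  # coefficients come from refitting
        assert {s.form for s in specs} >= {"binned_polynomial", "ann", "arrhenius",
                                           "autoregressive", "pressure_threshold",
                                           "linear"}


class TestRefit:
    def test_arrhenius_recovered_exactly_from_clean_data(self):
        rng = np.random.default_rng(0)
        temp = rng.uniform(16, 23, 500)
        y = 12.0 * np.exp(0.31 * (temp - 20.0))
        spec = ModelSpec(name="arr", form="arrhenius", timescale="1d",
                         predictors=["temp_bottom"])
        out = refit_model(spec, pd.DataFrame({"temp_bottom": temp}), y)
        assert out.coefficients["flux_at_20C"] == pytest.approx(12.0, rel=1e-6)
        assert out.coefficients["theta"] == pytest.approx(0.31, rel=1e-6)

    def test_threshold_recovered_within_five_percent_under_noise(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            p = rng.uniform(190, 215, 500)
            y = 4.0 * np.clip(205.0 - p, 0, None) + rng.normal(0, 1.0, 500)
            spec = ModelSpec(name="thr", form="pressure_threshold", timescale="1d",
                             predictors=["total_pressure"])
            out = refit_model(spec, pd.DataFrame({"total_pressure": p}), y)
            assert out.coefficients["rate_constant"] == pytest.approx(4.0, rel=0.05)
            assert out.coefficients["pressure_threshold"] == pytest.approx(205.0, rel=0.05)

    def test_constant_response_gives_zero_slope(self):
        x = np.linspace(0, 1, 100)
        spec = ModelSpec(name="lin", form="linear", timescale="1d", predictors=["x"])
        out = refit_model(spec, pd.DataFrame({"x": x}), np.full(100, 3.0))
        assert out.coefficients["x"] == pytest.approx(0.0, abs=1e-10)
        assert out.coefficients["intercept"] == pytest.approx(3.0)

    def test_refit_never_worsens_in_sample_rmse(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(16, 23, 300)
        y = 2.0 * x - 20 + rng.normal(0, 2, 300)
        table = pd.DataFrame({"temp_bottom": x})
        fixed = ModelSpec(name="lin", form="linear", timescale="1d",
                          predictors=["temp_bottom"],
                          coefficients={"intercept": 5.0, "temp_bottom": 1.0})
        refitted = refit_model(fixed, table, y)
        rmse_fixed = evaluate_model(y, predict_literature_model(fixed, table)).rmse
        rmse_refit = evaluate_model(y, predict_literature_model(refitted, table)).rmse
        assert rmse_refit <= rmse_fixed + 1e-12

    def test_too_few_rows_rejected(self):
        spec = ModelSpec(name="lin", form="linear", timescale="1d", predictors=["x"])
        with pytest.raises(ValueError, match="too few"):
            refit_model(spec, pd.DataFrame({"x": np.arange(5.0)}), np.arange(5.0))

    def test_ann_refit_beats_mean_forecast(self):
        rng = np.random.default_rng(3)
        n = 400
        table = pd.DataFrame({"d_total_pressure": rng.normal(0, 0.5, n),
                              "total_pressure": rng.uniform(200, 215, n),
                              "temp_bottom": rng.uniform(16, 23, n)})
        y = (10 * np.clip(-table["d_total_pressure"], 0, None)
             + 0.8 * (table["temp_bottom"] - 16) ** 2 + rng.normal(0, 1, n)).to_numpy()
        spec = ModelSpec(name="ann", form="ann", timescale="1d",
                         predictors=list(table.columns))
        out = refit_model(spec, table, y, seed=0)
        rep = evaluate_model(y, predict_literature_model(out, table))
        assert rep.nse > 0.5


class TestAdditiveModel:
    def test_linear_response_fit_almost_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 300)
        table = pd.DataFrame({"x": x, "z": rng.uniform(0, 1, 300)})
        y = 3.0 * x + 1.0
        gam = fit_gam(y, table)
        assert gam.r2() > 0.999

    def test_known_smooths_and_signal_fraction_recovered(self):
        rng = np.random.default_rng(1)
        n = 2000
        x1 = rng.uniform(-2, 2, n)
        x2 = rng.uniform(0, 4, n)
        f1 = np.sin(1.5 * x1)
        f2 = 0.25 * (x2 - 2.0) ** 2
        noise_sd = 0.3
        y = f1 + f2 + rng.normal(0, noise_sd, n)
        signal_var = f1.var() + f2.var()
        expected_r2 = signal_var / (signal_var + noise_sd**2)
        gam = fit_gam(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert gam.r2() == pytest.approx(expected_r2, abs=0.05)
        grid, shape = gam.partial_dependence("x1")
        truth = np.sin(1.5 * grid)
        np.testing.assert_allclose(shape - shape.mean(), truth - truth.mean(), atol=0.15)

    def test_overfitting_detector_fires_when_n_barely_exceeds_parameters(self):
        rng = np.random.default_rng(2)
        n = 25
        table = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)})
        y = rng.normal(size=n)
        gam = AdditiveModel(lambda_grid=np.array([1e-8])).fit(table, y)
        assert gam.r2() > 0.7                  # interpolation-like in-sample fit
        assert gam.predicted_r2() == 0.0       # PRESS flags it as overfit
        assert gam.predicted_r2() < gam.r2() - 0.5

    def test_zero_variance_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"x": rng.uniform(0, 1, 100), "c": np.ones(100)})
        with pytest.warns(UserWarning, match="zero-variance"):
            gam = fit_gam(3 * table["x"].to_numpy(), table)
        assert gam.terms_ == ["x"]

    def test_agrees_with_statsmodels_gam_on_smooth_signal(self):
        """Independent cross-check against a penalized-spline GAM from
        statsmodels on the same single-predictor problem."""
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        rng = np.random.default_rng(4)
        n = 800
        x = np.sort(rng.uniform(-3, 3, n))
        y = np.sin(x) + rng.normal(0, 0.25, n)
        table = pd.DataFrame({"x": x})
        ours = fit_gam(y, table)

        bs = BSplines(x[:, None], df=[10], degree=[3])
        sm_fit = GLMGam(y, np.ones((n, 1)), smoother=bs, alpha=[1.0]).fit()
        sm_pred = sm_fit.predict(np.ones((n, 1)), exog_smooth=x[:, None])
        our_pred = ours.predict(table)
        # both should track sin(x); they must agree with each other closely
        assert np.sqrt(np.mean((our_pred - sm_pred) ** 2)) < 0.1
        assert np.corrcoef(our_pred, sm_pred)[0, 1] > 0.99
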