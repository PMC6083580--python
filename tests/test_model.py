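"""Model frame, spline bases, tensor design and the quasi-Poisson fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heatvar as hv
from heatvar.model import assemble_design, sum_to_zero_transform
from oracles import natural_spline_cardinal, newton_poisson


def flat_series(start, periods, deaths=10, tmean=15.0):
    dates = pd.date_range(start, periods=periods, freq="D")
    return pd.DataFrame({"date": dates,
                         "deaths": np.full(periods, deaths),
                         "tmean": np.full(periods, float(tmean))})


class TestLaggedExposure:
    def test_lag_zero_is_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(hv.lagged_exposure(x, 0), x)

    def test_constant_series_invariant(self):
        np.testing.assert_allclose(hv.lagged_exposure(np.full(10, 7.0), 3)[3:], 7.0)

    def test_window_mean(self):
        out = hv.lagged_exposure([10.0, 20.0, 30.0, 40.0], 2)
        assert np.isnan(out[:2]).all()
        np.testing.assert_allclose(out[2:], [20.0, 30.0])

    def test_errors(self):
        with pytest.raises(ValueError):
            hv.lagged_exposure([1.0, 2.0], -1)
        with pytest.raises(ValueError):
            hv.lagged_exposure([1.0, 2.0], 2)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 5), st.integers(20, 60))
    def test_matches_direct_window_average(self, n, length):
        rng = np.random.default_rng(length * 7 + n)
        x = rng.normal(size=length)
        out = hv.lagged_exposure(x, n)
        for d in range(n, length):
            assert out[d] == pytest.approx(np.mean(x[d - n: d + 1]))


class TestBuildFrame:
    def test_two_year_series_dos_runs_1_to_183_twice(self):
        series = flat_series("1999-01-01", 365 * 2)
        frame = hv.build_frame(series, 0)
        assert len(frame) == 2 * 183
        np.testing.assert_array_equal(
            frame["dos"].to_numpy(), np.tile(np.arange(1, 184), 2))

    def test_constant_winter_deaths_give_that_wdd(self):
        series = flat_series("1999-01-01", 365 * 2, deaths=10)
        frame = hv.build_frame(series, 0)
        assert (frame["wdd"] == 10.0).all()

    def test_april_start_drops_first_season(self):
        dates = pd.date_range("2000-04-01", "2001-12-31", freq="D")
        series = pd.DataFrame({"date": dates, "deaths": 5,
                               "tmean": 15.0})
        frame = hv.build_frame(series, 0)
        assert frame["year"].min() == 2001

    def test_lag_uses_late_march_temperatures(self):
        series = flat_series("1999-01-01", 365 * 2)
        series.loc[series["date"] == "1999-03-31", "tmean"] = 30.0
        frame = hv.build_frame(series, 1)
        april1 = frame[(frame["year"] == 1999) & (frame["dos"] == 1)]
        assert april1["tmean_n"].iloc[0] == pytest.approx((30.0 + 15.0) / 2)

    def test_gap_rejected(self):
        series = flat_series("1999-01-01", 365 * 2).drop(index=100)
        with pytest.raises(ValueError, match="contiguous"):
            hv.build_frame(series, 0)


class TestCrsBasis:
    def test_rows_at_knots_are_unit_vectors(self):
        knots = np.array([0.0, 1.0, 3.0, 7.0])
        basis = hv.crs_basis(knots, knots)
        np.testing.assert_allclose(basis, np.eye(4), atol=1e-12)

    def test_reproduces_linear_functions(self):
        knots = np.array([0.0, 2.0, 5.0, 10.0])
        x = np.linspace(0, 10, 50)
        coef = 2.0 * knots + 1.0  # values of f(t)=2t+1 at the knots
        np.testing.assert_allclose(hv.crs_basis(x, knots) @ coef,
                                   2.0 * x + 1.0, atol=1e-10)

    def test_partition_of_unity(self):
        knots = np.array([-1.0, 0.5, 2.0, 4.0, 8.0])
        basis = hv.crs_basis(np.linspace(-1, 8, 33), knots)
        np.testing.assert_allclose(basis.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_truncated_power_construction(self):
        """Cross-implementation oracle: the scipy-based cardinal basis must
        agree with an independent textbook natural-spline construction."""
        knots = np.array([1.0, 4.0, 9.0, 16.0, 25.0])
        x = np.linspace(1, 25, 100)
        np.testing.assert_allclose(hv.crs_basis(x, knots),
                                   natural_spline_cardinal(x, knots),
                                   atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            hv.crs_basis([0.5], [0.0, 1.0])
        with pytest.raises(ValueError):
            hv.crs_basis([0.5], [0.0, 1.0, 1.0, 2.0])


class TestTensorDesign:
    def test_dimensions(self):
        block = hv.tensor_design(np.ones((10, 2)), np.ones((10, 3)))
        assert block.shape == (10, 6)

    def test_constant_time_column_degenerates_to_temp_basis(self):
        rng = np.random.default_rng(0)
        bt = rng.normal(size=(20, 4))
        block = hv.tensor_design(bt, np.ones((20, 1)))
        np.testing.assert_array_equal(block, bt)

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hv.tensor_design(np.ones((5, 2)), np.ones((6, 2)))

    def test_full_rank_on_simulated_city(self, small_city):
        frame = small_city["frame"]
        spec = hv.BasisSpec.from_frame(frame)
        bt = hv.crs_basis(frame["tmean_n"].to_numpy(), spec.temp_knots)
        bs = hv.crs_basis(frame["time"].to_numpy(), spec.time_knots)
        block = hv.tensor_design(bt, bs)
        assert np.linalg.matrix_rank(block) == block.shape[1]

    def test_sum_to_zero_transform_properties(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(50, 6)) + 1.0
        reduced, z = sum_to_zero_transform(block)
        assert reduced.shape == (50, 5)
        np.testing.assert_allclose(z.T @ z, np.eye(5), atol=1e-12)
        # every fitted contribution has zero mean over the rows
        np.testing.assert_allclose(reduced.mean(axis=0), 0.0, atol=1e-10)

    def test_design_spans_time_constant_heat_effect(self, small_city):
        """The reduced tensor block must still represent a temperature-only
        function (up to a constant absorbed by the intercept): project a
        hockey-stick of the exposure onto the block and check the residual
        is constant."""
        frame = small_city["frame"]
        spec = hv.BasisSpec.from_frame(frame)
        bt = hv.crs_basis(frame["tmean_n"].to_numpy(), spec.temp_knots)
        bs = hv.crs_basis(frame["time"].to_numpy(), spec.time_knots)
        reduced, _ = sum_to_zero_transform(hv.tensor_design(bt, bs))
        # target: spline-representable pure-temperature function
        target = bt @ np.array([0.0, 0.5, 1.5, 4.0])
        design = np.column_stack([np.ones(len(frame)), reduced])
        resid = target - design @ np.linalg.lstsq(design, target, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-8


class TestFitModel:
    def test_constant_deaths_null_fit(self):
        rng = np.random.default_rng(0)
        series = flat_series("1995-01-01", 365 * 4, deaths=20)
        series["tmean"] = 15.0 + 10.0 * np.sin(np.arange(len(series)) / 58.0) \
            + rng.normal(0, 1, len(series))
        frame = hv.build_frame(series, 3)
        model = hv.fit_model(frame)
        assert model.params[0] == pytest.approx(np.log(20.0), abs=1e-6)
        t = float(frame["time"].iloc[200])
        logrr, se = hv.predict_logrr(model, model.percentiles["p90"] + 1,
                                     model.percentiles["p90"], t)
        assert logrr == pytest.approx(0.0, abs=1e-6)

    def test_irls_matches_newton_oracle_small_instance(self):
        """On a small dense instance the statsmodels IRLS fit must agree
        with an independent Newton-Raphson solve to 1e-6 relative."""
        rng = np.random.default_rng(7)
        n, p = 400, 6
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta_true = np.array([2.0, 0.3, -0.2, 0.1, 0.05, -0.4])
        y = rng.poisson(np.exp(X @ beta_true))
        import statsmodels.api as sm
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(
            maxiter=100, tol=1e-10)
        oracle = newton_poisson(X, y)
        np.testing.assert_allclose(res.params, oracle, rtol=1e-6)

    def test_dispersion_scales_contrast_variance(self, small_city):
        model = small_city["model"]
        import copy
        doubled = copy.deepcopy(model)
        doubled.cov = model.cov * 2.0
        t = float(model.times[100])
        _, se1 = hv.predict_logrr(model, model.percentiles["p90"] + 2,
                                  model.percentiles["p90"], t, clamp=True)
        _, se2 = hv.predict_logrr(doubled, model.percentiles["p90"] + 2,
                                  model.percentiles["p90"], t, clamp=True)
        assert se2 == pytest.approx(se1 * np.sqrt(2.0), rel=1e-12)

    def test_serialization_roundtrip(self, small_city, tmp_path):
        model = small_city["model"]
        model.save(tmp_path / "m.json")
        back = hv.FittedModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.params, model.params, atol=1e-12)
        np.testing.assert_allclose(back.cov, model.cov, atol=1e-12)
        np.testing.assert_allclose(back.z_tensor, model.z_tensor, atol=1e-12)
        t = float(model.times[50])
        a = hv.predict_logrr(model, 25.0, 20.0, t, clamp=True)
        b = hv.predict_logrr(back, 25.0, 20.0, t, clamp=True)
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_and_short_frames_rejected(self, small_city):
        with pytest.raises(ValueError):
            hv.fit_model(small_city["frame"].iloc[:0])
        one_year = small_city["frame"].query("year == 1991")
        with pytest.raises(ValueError):
            hv.fit_model(one_year)


class TestPredictLogrr:
    def test_identical_temperatures_give_exact_zero(self, small_city):
        model = small_city["model"]
        assert hv.predict_logrr(model, 22.0, 22.0, 100.0) == (0.0, 0.0)

    def test_extrapolation_rejected_unless_clamped(self, small_city):
        model = small_city["model"]
        hi = model.percentiles["max"]
        with pytest.raises(ValueError, match="outside fitted range"):
            hv.predict_logrr(model, hi + 5.0, hi - 2.0, 100.0)
        logrr, se = hv.predict_logrr(model, hi + 5.0, hi - 2.0, 100.0,
                                     clamp=True)
        assert np.isfinite(logrr) and se >= 0

    def test_se_agrees_with_parametric_bootstrap(self, strong_city):
        """The delta-method contrast SE must agree with the SD of the
        contrast under 200 parametric-bootstrap draws of the coefficients."""
        model = strong_city["model"]
        t = float(np.median(model.times))
        t0 = model.percentiles["p90"]
        logrr, se = hv.predict_logrr(model, t0 + 2.0, t0, t, clamp=True)
        rng = np.random.default_rng(0)
        a, b = model.layout["tensor"]
        theta = rng.multivariate_normal(model.params[a:b],
                                        model.cov[a:b, a:b], size=200,
                                        method="cholesky")
        rows = (model.tensor_row(np.array([t0 + 2.0]), np.array([t]))
                - model.tensor_row(np.array([t0]), np.array([t])))
        draws = theta @ rows[0]
        ratio = np.std(draws, ddof=1) / se
        assert 0.8 < ratio < 1.25
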