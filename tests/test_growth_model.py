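"""Growth-model unit and property tests: clipped temperature sums, the
sigmoid curve and its inverse, fitting, anchoring and swap validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from headcast.errors import (
    DomainError,
    FitError,
    InvalidDataError,
    MissingDataError,
    UndefinedMetricError,
)
from headcast.growth_model import (
    GrowthModelParams,
    TemperatureSeries,
    anchor_drone_series,
    build_prediction_model,
    fit_growth_model,
    fit_init_model,
    invert_model,
    predict_hd,
    swap_validate,
)

from .conftest import const_temps


class TestClippedTempSum:
    def test_clipping_limits(self):
        ts = TemperatureSeries(["2020-05-01", "2020-05-02", "2020-05-03"], [-2.0, 10.0, 25.0])
        assert ts.clipped_sum("2020-04-30", "2020-05-03") == pytest.approx(30.0)

    def test_upper_boundary(self):
        n = 14
        ts = const_temps(20.0, "2020-05-01", "2020-05-14")
        assert ts.clipped_sum("2020-04-30", "2020-05-14") == pytest.approx(20.0 * n)

    def test_may_at_monthly_mean(self, temps_warm):
        # 31 days at the May monthly mean of 19.6 degC
        assert temps_warm.clipped_sum("2020-04-30", "2020-05-31") == pytest.approx(607.6)

    def test_empty_window_and_uncovered_window(self, temps_warm):
        assert temps_warm.clipped_sum("2020-05-10", "2020-05-10") == 0.0
        with pytest.raises(MissingDataError):
            temps_warm.clipped_sum("2020-05-10", "2020-07-15")
        with pytest.raises(MissingDataError):
            temps_warm.clipped_sum("2020-05-10", "2020-05-05")

    def test_gapped_series_rejected(self):
        with pytest.raises(InvalidDataError):
            TemperatureSeries(["2020-05-01", "2020-05-03"], [10.0, 11.0])

    @given(
        temps=st.lists(st.floats(-15, 40), min_size=4, max_size=40),
        split_frac=st.floats(0.1, 0.9),
    )
    def test_additive_and_bounded(self, temps, split_frac):
        idx = pd.date_range("2020-04-01", periods=len(temps), freq="D")
        ts = TemperatureSeries(idx, temps)
        start, end = idx[0] - pd.Timedelta(days=1), idx[-1]
        mid = idx[int(split_frac * (len(temps) - 1))]
        total = ts.clipped_sum(start, end)
        assert total == pytest.approx(ts.clipped_sum(start, mid) + ts.clipped_sum(mid, end))
        assert 0.0 <= total <= 20.0 * len(temps)


class TestCurveAndInverse:
    def test_startup_size_within_band(self, params_2020, params_2021):
        # head diameter at T = 0 must sit in the 3-3.5 cm startup band
        for p in (params_2020, params_2021):
            assert 30.0 <= predict_hd(p, 0.0) <= 35.0

    def test_asymptote_limit(self, params_2020):
        assert predict_hd(params_2020, 1e9) == pytest.approx(np.exp(params_2020.a))

    def test_strictly_increasing(self, params_2020):
        grid = np.linspace(-500, 2000, 800)
        hd = predict_hd(params_2020, grid)
        assert np.all(np.diff(hd) > 0)
        assert np.all(hd < np.exp(params_2020.a))

    def test_invert_at_startup_is_zero(self, params_2020):
        assert invert_model(params_2020, params_2020.startup_hd_mm) == pytest.approx(0.0, abs=1e-9)

    def test_invert_first_flight_diameter(self, params_2020):
        # 9.5 cm head, cross-checked by root-finding on the forward curve
        t_closed = invert_model(params_2020, 95.0)
        t_root = brentq(lambda t: predict_hd(params_2020, t) - 95.0, -1000, 5000, xtol=1e-10)
        assert t_closed == pytest.approx(t_root, abs=1e-6)
        assert t_closed == pytest.approx(135.9, abs=0.1)

    def test_round_trip_identity(self, params_2020):
        hd = np.linspace(1.0, np.exp(params_2020.a) - 1.0, 500)
        back = predict_hd(params_2020, invert_model(params_2020, hd))
        assert np.allclose(back, hd, rtol=1e-9)

    def test_domain_errors(self, params_2020):
        with pytest.raises(DomainError):
            invert_model(params_2020, np.exp(params_2020.a))  # at the asymptote
        with pytest.raises(DomainError):
            invert_model(params_2020, -5.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidDataError):
            GrowthModelParams(a=5.5, b=-1.0, c=0.005)


class TestFit:
    def test_noiseless_recovery(self, params_2020):
        t = np.linspace(0, 600, 24)
        hd = predict_hd(params_2020, t)
        fit = fit_growth_model(t, hd)
        for name in ("a", "b", "c"):
            assert getattr(fit, name) == pytest.approx(getattr(params_2020, name), rel=1e-6)

    def test_under_determined(self):
        with pytest.raises(FitError):
            fit_growth_model([0.0, 100.0], [33.0, 60.0])
        with pytest.raises(FitError):
            fit_growth_model([50.0] * 6, [40.0] * 6)  # degenerate T range

    def test_nonpositive_hd_rejected(self):
        with pytest.raises(InvalidDataError):
            fit_growth_model([0, 100, 200, 300], [30, -1, 90, 120])

    def test_order_invariance(self, params_2020):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 600, 40)
        hd = predict_hd(params_2020, t) * np.exp(rng.normal(0, 0.05, t.size))
        fit1 = fit_growth_model(t, hd)
        perm = rng.permutation(t.size)
        fit2 = fit_growth_model(t[perm], hd[perm])
        assert fit1.a == pytest.approx(fit2.a, rel=1e-8)
        assert fit1.c == pytest.approx(fit2.c, rel=1e-8)


class TestAnchoring:
    def test_zero_temperature_increment(self, params_2020):
        cold = const_temps(-5.0, "2020-05-01", "2020-05-31")  # clipped to 0 degC-day
        table = pd.DataFrame(
            {"plant_id": [1, 1], "date": ["2020-05-10", "2020-05-20"], "hd_mm": [95.0, 95.0]}
        )
        anchored = anchor_drone_series(table, params_2020, cold)
        t = anchored.data["t_sum"].to_numpy()
        assert t[1] == pytest.approx(t[0])

    def test_beyond_asymptote_excluded_and_logged(self, params_2020, temps_warm, caplog):
        table = pd.DataFrame(
            {
                "plant_id": [1, 2],
                "date": ["2020-05-18", "2020-05-18"],
                "hd_mm": [95.0, np.exp(params_2020.a) + 1.0],
            }
        )
        with caplog.at_level("WARNING"):
            anchored = anchor_drone_series(table, params_2020, temps_warm)
        assert list(anchored.excluded["plant_id"]) == [2]
        assert 2 not in anchored.t0 and 1 in anchored.t0
        assert any("excluded" in r.message for r in caplog.records)

    def test_t0_reproduces_induction_offsets(self, params_2020, temps_warm):
        # noiseless, occlusion-free observations anchored with the true model
        # recover each plant's thermal-time offset exactly
        rng = np.random.default_rng(11)
        offsets = rng.normal(0, 30, 40)
        base_t = temps_warm.clipped_sum("2020-05-11", "2020-05-18")
        hd = predict_hd(params_2020, base_t + offsets)
        table = pd.DataFrame(
            {"plant_id": np.arange(40), "date": ["2020-05-18"] * 40, "hd_mm": hd}
        )
        anchored = anchor_drone_series(table, params_2020, temps_warm)
        t0 = np.array([anchored.t0[i] for i in range(40)])
        assert np.allclose(t0 - base_t, offsets, atol=1e-8)


class TestPredictionModel:
    def test_noiseless_pooled_recovery(self, params_2020, temps_warm):
        dates = ["2020-05-18", "2020-05-21", "2020-05-24", "2020-05-27"]
        rng = np.random.default_rng(4)
        offsets = rng.normal(0, 30, 30)
        rows = []
        for pid, off in enumerate(offsets):
            for d in dates:
                t = temps_warm.clipped_sum("2020-05-11", d) + off
                rows.append({"plant_id": pid, "date": d, "hd_mm": predict_hd(params_2020, t)})
        anchored = anchor_drone_series(pd.DataFrame(rows), params_2020, temps_warm)
        fit = build_prediction_model(anchored)
        for name in ("a", "b", "c"):
            assert getattr(fit, name) == pytest.approx(getattr(params_2020, name), rel=1e-6)

    def test_empty_input(self):
        from headcast.growth_model import AnchoredSeries

        with pytest.raises(InvalidDataError):
            build_prediction_model(AnchoredSeries(data=pd.DataFrame()))


class TestInitModel:
    def test_startup_band_alignment_recovers_curve(self, params_2020, temps_warm):
        # plants crossing the 30-35 mm band on different dates, measured on a
        # shared calendar, pool into one T-aligned curve
        dates = pd.date_range("2020-05-05", "2020-05-29", freq="2D")
        rng = np.random.default_rng(9)
        offsets = rng.normal(0, 30, 60)
        origin = pd.Timestamp("2020-05-11")
        rows = []
        for pid, off in enumerate(offsets):
            for d in dates:
                t = (
                    temps_warm.clipped_sum(origin, d)
                    if d >= origin
                    else -temps_warm.clipped_sum(d, origin)
                ) + off
                rows.append(
                    {"plant_id": pid, "date": d, "hd_mm": predict_hd(params_2020, t)}
                )
        params, info = fit_init_model(pd.DataFrame(rows), temps_warm)
        assert info["n_plants_used"] > 0
        # band quantisation (measurements every 2 days) leaves a small bias
        assert params.a == pytest.approx(params_2020.a, rel=0.02)
        assert params.c == pytest.approx(params_2020.c, rel=0.10)

    def test_no_plant_in_band(self, params_2020, temps_warm):
        rows = pd.DataFrame(
            {"plant_id": [1, 1, 1, 1], "date": ["2020-05-18", "2020-05-20", "2020-05-22",
                                                "2020-05-24"], "hd_mm": [90, 100, 110, 120]}
        )
        with pytest.raises(InvalidDataError):
            fit_init_model(rows, temps_warm)


class TestSwapValidation:
    @staticmethod
    def _drone_table(params, temps, dates, offsets, noise_sd, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for pid, off in enumerate(offsets):
            for d in dates:
                t = temps.clipped_sum("2020-05-11", d) + off
                hd = predict_hd(params, t) + rng.normal(0, noise_sd)
                rows.append({"plant_id": pid, "date": d, "hd_mm": hd})
        return pd.DataFrame(rows)

    def test_identical_years_near_perfect(self, params_2020, temps_warm):
        rng = np.random.default_rng(2)
        offsets = rng.normal(0, 30, 25)
        table = self._drone_table(params_2020, temps_warm, ["2020-05-18", "2020-05-22"],
                                  offsets, 0.0, 0)
        result = swap_validate(params_2020, table, params_2020, temps_warm)
        assert (result["r2"] > 0.999).all()
        assert (result["rmse_mm"] < 1e-6).all()

    def test_rate_mismatch_degrades_late_window(self, temps_warm):
        # two seasons differing in the thermal rate c: the cross-year model
        # correlates well early but poorly once growth saturates
        model_a = GrowthModelParams(a=5.75, b=2.33, c=0.00475)
        truth_b = GrowthModelParams(a=5.58, b=1.94, c=0.00616)
        init_b = truth_b
        rng = np.random.default_rng(7)
        offsets = rng.normal(0, 30, 150)
        dates = ["2020-05-18", "2020-05-22", "2020-05-30", "2020-06-07", "2020-06-15"]
        table = self._drone_table(truth_b, temps_warm, dates, offsets, 3.0, 1)
        result = swap_validate(model_a, table, init_b, temps_warm).sort_values("date")
        assert result["r2"].iloc[0] > result["r2"].iloc[-1]

    def test_single_plant_errors(self, params_2020, temps_warm):
        table = pd.DataFrame(
            {"plant_id": [1, 1], "date": ["2020-05-18", "2020-05-22"], "hd_mm": [95.0, 120.0]}
        )
        with pytest.raises(UndefinedMetricError):
            swap_validate(params_2020, table, params_2020, temps_warm)
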