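"""Calibration, warming effect, Q10 fitting, CV, aggregation, coverage."""

import numpy as np
import pandas as pd
import pytest

from chamberflux import (
    CalibrationSet,
    GRAMS_C_PER_UMOL_HOUR,
    SiteForcing,
    TrueFluxModel,
    aggregate,
    calibrate_qc,
    chamber_cv,
    daily_coverage,
    default_chamber_meta,
    fit_q10,
    missing_fraction,
    warming_effect,
)
from chamberflux.synthetic import hourly_truth, soil_temperature


def _flux_df(rows):
    df = pd.DataFrame(rows, columns=["chamber", "treatment", "timestamp", "flux_umol_m2_s"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["usable"] = True
    return df


def _hourly_frames(
    fe=0.0,
    offsets=None,
    seed=0,
    noise_sd=0.0,
    start="2009-01-01",
    warming_start="2009-01-19",
    end="2009-06-01",
    warming_offset=2.5,
):
    """Hour-level synthetic experiment: 5 trenched + 5 warmed-trenched
    chambers with multiplicative offsets, warming applied after onset."""
    rng = np.random.default_rng(seed)
    f = SiteForcing(warming_offset_c=warming_offset)
    m = TrueFluxModel(fe_pct_per_c=fe)
    base = hourly_truth(f, m, start, end, treatment="trenched")
    times = pd.to_datetime(base["timestamp"])
    active = (times >= pd.Timestamp(warming_start)).to_numpy()
    rows, env_rows = [], []
    offsets = offsets or {}
    for ch in range(6, 16):
        warmed = ch >= 11
        off = offsets.get(ch, float(np.exp(rng.normal(0, 0.2))))
        flux = base["flux"].to_numpy() * off
        if warmed:
            flux = flux * (1 + fe * warming_offset / 100.0 * active)
        if noise_sd:
            flux = flux * np.exp(rng.normal(0, noise_sd, len(flux)))
        tr = "warmed_trenched" if warmed else "trenched"
        rows.append(
            pd.DataFrame(
                {
                    "chamber": ch,
                    "treatment": tr,
                    "timestamp": times,
                    "flux_umol_m2_s": flux,
                    "usable": True,
                }
            )
        )
        env_rows.append(
            pd.DataFrame(
                {
                    "timestamp": times,
                    "chamber": ch,
                    "t_soil_c": base["t_soil"].to_numpy() + warming_offset * active * warmed,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), pd.concat(env_rows, ignore_index=True)


class TestCalibration:
    def test_identical_chambers_give_unit_qc(self):
        ts = pd.date_range("2009-01-01", periods=48, freq="h")
        rows = [
            (ch, tr, t, 2.0)
            for t in ts
            for ch, tr in [(6, "trenched"), (7, "trenched"), (11, "warmed_trenched")]
        ]
        calib = calibrate_qc(_flux_df(rows), ("2009-01-01", "2009-01-03"))
        assert calib.qc["trenched"] == pytest.approx(1.0)
        assert calib.qc["warmed_trenched"] == pytest.approx(1.0)

    def test_simple_ratio(self):
        """All-trenched mean 2.0 vs warmed-group mean 1.6 gives Qcw = 1.25."""
        ts = pd.date_range("2009-01-01", periods=24, freq="h")
        rows = [(6, "trenched", t, 2.4) for t in ts] + [(11, "warmed_trenched", t, 1.6) for t in ts]
        calib = calibrate_qc(_flux_df(rows), ("2009-01-01", "2009-01-02"))
        assert calib.qc["warmed_trenched"] == pytest.approx(2.0 / 1.6)
        assert calib.qc["trenched"] == pytest.approx(2.0 / 2.4)

    def test_empty_window_is_error(self):
        ts = pd.date_range("2009-01-01", periods=4, freq="h")
        df = _flux_df([(6, "trenched", t, 2.0) for t in ts])
        with pytest.raises(ValueError):
            calibrate_qc(df, ("2010-01-01", "2010-02-01"))

    def test_missing_treatment_is_error(self):
        ts = pd.date_range("2009-01-01", periods=4, freq="h")
        df = _flux_df([(6, "trenched", t, 2.0) for t in ts])
        with pytest.raises(ValueError, match="warmed_trenched"):
            calibrate_qc(df, ("2009-01-01", "2009-01-02"))

    def test_offsets_aligned_after_calibration(self):
        """With spatial offsets but no treatment effect, Qc-calibrated group
        means agree to Monte-Carlo error."""
        flux_df, _ = _hourly_frames(fe=0.0, seed=4, noise_sd=0.05)
        calib = calibrate_qc(flux_df, ("2009-01-01", "2009-01-19"))
        post = flux_df[flux_df["timestamp"] >= "2009-01-19"]
        means = post.groupby("treatment")["flux_umol_m2_s"].mean()
        ratio = (calib.qc["warmed_trenched"] * means["warmed_trenched"]) / (
            calib.qc["trenched"] * means["trenched"]
        )
        assert ratio == pytest.approx(1.0, abs=0.01)


class TestWarmingEffect:
    def _meta(self):
        return default_chamber_meta(15)

    def test_equal_calibrated_fluxes_give_zero(self):
        flux_df, env_df = _hourly_frames(fe=0.0, offsets={ch: 1.0 for ch in range(6, 16)})
        calib = CalibrationSet(
            qc={"trenched": 1.0, "warmed_trenched": 1.0},
            window=(pd.Timestamp("2009-01-01"), pd.Timestamp("2009-01-19")),
        )
        we = warming_effect(flux_df, env_df, calib, self._meta(), ("2009-01-19", "2009-06-01"))
        assert we.fe_pct_per_c == pytest.approx(0.0, abs=1e-9)
        assert we.delta_t_c == pytest.approx(2.5)

    def test_textbook_arithmetic(self):
        """Rh=2.0, Rhw=2.5, dT=2.5 degC, unit Qc: Fe = 10 % per degC."""
        ts = pd.date_range("2009-02-01", periods=240, freq="h")
        rows = [(6, "trenched", t, 2.0) for t in ts] + [(11, "warmed_trenched", t, 2.5) for t in ts]
        env = pd.concat(
            [
                pd.DataFrame({"timestamp": ts, "chamber": 6, "t_soil_c": 10.0}),
                pd.DataFrame({"timestamp": ts, "chamber": 11, "t_soil_c": 12.5}),
            ],
            ignore_index=True,
        )
        calib = CalibrationSet(
            qc={"trenched": 1.0, "warmed_trenched": 1.0},
            window=(pd.Timestamp("2009-01-01"), pd.Timestamp("2009-01-19")),
        )
        we = warming_effect(_flux_df(rows), env, calib, self._meta(), ("2009-02-01", "2009-03-01"))
        assert we.fe_pct_per_c == pytest.approx(10.0)

    def test_zero_delta_t_is_error(self):
        flux_df, env_df = _hourly_frames(fe=5.0, warming_offset=0.0)
        calib = CalibrationSet(
            qc={"trenched": 1.0, "warmed_trenched": 1.0},
            window=(pd.Timestamp("2009-01-01"), pd.Timestamp("2009-01-19")),
        )
        with pytest.raises(ValueError, match="undefined|~ 0"):
            warming_effect(flux_df, env_df, calib, self._meta(), ("2009-01-19", "2009-06-01"))

    def test_pre_warming_effect_is_zero(self):
        """Estimated over the pre-treatment window, Fe vanishes."""
        flux_df, env_df = _hourly_frames(fe=9.4, seed=2, noise_sd=0.05)
        calib = calibrate_qc(flux_df, ("2009-01-01", "2009-01-19"))
        # evaluate over the calibration window itself: no warming active yet,
        # so use the unwarmed soil temperatures plus a nominal offset column
        env_pre = env_df[env_df["timestamp"] < "2009-01-19"].copy()
        env_pre.loc[env_pre["chamber"] >= 11, "t_soil_c"] += 2.5  # sensors read warm plots
        we = warming_effect(flux_df, env_pre, calib, self._meta(), ("2009-01-01", "2009-01-19"))
        assert we.fe_pct_per_c == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("true_fe", [5.0, 9.4, 15.0])
    def test_fe_recovery_grid(self, true_fe):
        """Across true Fe of 5/9.4/15 % per degC the estimate lands within
        one percentage point per degC and preserves rank order."""
        flux_df, env_df = _hourly_frames(fe=true_fe, seed=3, noise_sd=0.1)
        calib = calibrate_qc(flux_df, ("2009-01-01", "2009-01-19"))
        we = warming_effect(flux_df, env_df, calib, self._meta(), ("2009-01-19", "2009-06-01"))
        assert we.fe_pct_per_c == pytest.approx(true_fe, abs=1.0)

    def test_hourly_mode_agrees_with_period_mean(self):
        flux_df, env_df = _hourly_frames(fe=9.4, seed=5)
        calib = calibrate_qc(flux_df, ("2009-01-01", "2009-01-19"))
        a = warming_effect(flux_df, env_df, calib, self._meta(), ("2009-01-19", "2009-06-01"))
        b = warming_effect(
            flux_df, env_df, calib, self._meta(), ("2009-01-19", "2009-06-01"), mode="hourly"
        )
        assert b.fe_pct_per_c == pytest.approx(a.fe_pct_per_c, abs=1.0)


class TestQ10:
    def test_noise_free_closed_form(self):
        """R = 2 * 2.5^((T-10)/10) over 5..25 degC returns Q10 = 2.5 exactly."""
        t = np.linspace(5, 25, 200)
        r = 2.0 * 2.5 ** ((t - 10) / 10)
        fit = fit_q10(r, t)
        assert fit.q10 == pytest.approx(2.5, rel=1e-12)
        assert fit.flux_ref == pytest.approx(2.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_temperature_unidentifiable(self):
        with pytest.raises(ValueError, match="span"):
            fit_q10(np.full(100, 2.0), np.full(100, 15.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="few"):
            fit_q10(np.array([1.0, 2.0]), np.array([5.0, 25.0]))

    def test_non_positive_fluxes_excluded_and_counted(self):
        t = np.linspace(5, 25, 100)
        r = 2.0 * 2.5 ** ((t - 10) / 10)
        r[::10] = -0.1
        fit = fit_q10(r, t)
        assert fit.n_excluded == 10
        assert fit.q10 == pytest.approx(2.5, rel=1e-9)

    def test_nls_agrees_with_ols_on_clean_data(self):
        """The nonlinear route is an independent cross-check of the log-linear fit."""
        t = np.linspace(2, 28, 300)
        r = 1.5 * 2.8 ** ((t - 10) / 10)
        ols = fit_q10(r, t, method="ols")
        nls = fit_q10(r, t, method="nls")
        assert nls.q10 == pytest.approx(ols.q10, rel=1e-6)
        assert nls.flux_ref == pytest.approx(ols.flux_ref, rel=1e-6)

    def test_recovery_bias_over_replicates(self):
        """50 seeded year-long replicates at lognormal noise sd 0.1: every
        estimate within +/-0.1 of truth and mean bias below 0.05."""
        f, m = SiteForcing(), TrueFluxModel(q10=2.5)
        est = []
        for rep in range(50):
            h = hourly_truth(f, m, "2009-01-01", "2010-01-01", noise_sd=0.1, seed=1000 + rep)
            fit = fit_q10(h["flux"], h["t_soil"])
            est.append(fit.q10)
        est = np.asarray(est)
        assert np.all(np.abs(est - 2.5) < 0.1)
        assert abs(est.mean() - 2.5) < 0.05


class TestChamberCV:
    def _df(self, values, ts=None):
        ts = ts or pd.date_range("2009-07-08", periods=1, freq="h")
        rows = []
        for t in ts:
            rows += [(ch, "control", t, v) for ch, v in enumerate(values, start=1)]
        return _flux_df(rows)

    def test_identical_chambers_zero_cv(self):
        res = chamber_cv(self._df([2.0, 2.0, 2.0]), "control")
        assert res.mean_cv_pct == pytest.approx(0.0)

    def test_two_chamber_arithmetic(self):
        """Chambers at 1.0 and 3.0: sample sd / mean = 70.7%."""
        res = chamber_cv(self._df([1.0, 3.0]), "control")
        assert res.mean_cv_pct == pytest.approx(100 * np.sqrt(2) / 2, abs=1e-9)

    def test_hot_spot_exclusion_lowers_cv(self):
        values = [1.0, 1.1, 0.9, 1.05, 5.0]  # chamber 5 is a hot spot
        with_hot = chamber_cv(self._df(values), "control")
        without = chamber_cv(self._df(values), "control", exclude=[5])
        assert without.mean_cv_pct < with_hot.mean_cv_pct

    def test_zero_mean_hours_skipped(self):
        ts = pd.date_range("2009-07-08", periods=2, freq="h")
        rows = [(1, "control", ts[0], 1.0), (2, "control", ts[0], 3.0),
                (1, "control", ts[1], 0.0), (2, "control", ts[1], 0.0)]
        res = chamber_cv(_flux_df(rows), "control")
        assert res.n_hours == 1 and res.n_skipped == 1


class TestAggregation:
    def test_constant_flux_year(self):
        """1 umol m-2 s-1 for 365 days = 378.8 g C m-2 = 3.788 t C ha-1."""
        idx = pd.date_range("2009-01-01", periods=365 * 24, freq="h")
        res = aggregate(pd.Series(1.0, index=idx))
        assert GRAMS_C_PER_UMOL_HOUR == pytest.approx(0.0432396)
        assert res.total_g_c_m2 == pytest.approx(378.8, abs=0.05)
        assert res.total_t_c_ha == pytest.approx(3.788, abs=5e-4)
        assert res.annual_t_c_ha == pytest.approx(res.total_t_c_ha, rel=1e-12)

    def test_zero_flux_year(self):
        idx = pd.date_range("2009-01-01", periods=100 * 24, freq="h")
        res = aggregate(pd.Series(0.0, index=idx))
        assert res.total_g_c_m2 == 0.0

    def test_daily_sums_add_to_total_exactly(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2009-01-01", periods=40 * 24, freq="h")
        res = aggregate(pd.Series(rng.uniform(0, 5, len(idx)), index=idx))
        assert res.daily["g_c_m2"].sum() == pytest.approx(res.total_g_c_m2, rel=1e-12)

    def test_gap_fill_recovers_annual_sum_within_two_percent(self):
        """5% of hours dropped and refilled from the fitted Q10 response."""
        f, m = SiteForcing(), TrueFluxModel()
        h = hourly_truth(f, m, "2009-01-01", "2010-01-01", noise_sd=0.05, seed=9)
        s = pd.Series(h["flux"].to_numpy(), index=pd.DatetimeIndex(h["timestamp"]))
        t = pd.Series(h["t_soil"].to_numpy(), index=s.index)
        full = aggregate(s)
        rng = np.random.default_rng(10)
        gaps = rng.choice(len(s), size=int(0.05 * len(s)), replace=False)
        gappy = s.copy()
        gappy.iloc[gaps] = np.nan
        gappy = gappy.dropna()
        fit = fit_q10(gappy.to_numpy(), t.loc[gappy.index].to_numpy())
        filled = aggregate(gappy, q10_fit=fit, t_soil=t)
        assert filled.fill_fraction == pytest.approx(0.05, abs=0.005)
        assert filled.total_g_c_m2 == pytest.approx(full.total_g_c_m2, rel=0.02)

    def test_gap_fill_without_temperature_is_error(self):
        idx = pd.date_range("2009-01-01", periods=48, freq="h")
        s = pd.Series(1.0, index=idx).drop(idx[5])
        f, m = SiteForcing(), TrueFluxModel()
        h = hourly_truth(f, m, "2009-01-01", "2009-03-01")
        fit = fit_q10(h["flux"], h["t_soil"])
        with pytest.raises(ValueError, match="temperature"):
            aggregate(s, q10_fit=fit)


class TestCoverage:
    def test_printed_arithmetic(self):
        """105 missing of 2,202 measurement days is 4.8%."""
        res = missing_fraction(105, 2202)
        assert res.pct == 4.8

    def test_extremes(self):
        assert missing_fraction(0, 100).pct == 0.0
        assert missing_fraction(100, 100).pct == 100.0

    def test_daily_coverage_classification(self):
        ts = pd.date_range("2009-01-01", periods=3 * 24, freq="h")
        df = _flux_df([(1, "control", t, 1.0) for t in ts])
        # day 2 loses most of its usable closures
        day2 = (df["timestamp"] >= "2009-01-02") & (df["timestamp"] < "2009-01-03")
        df.loc[day2 & (df["timestamp"].dt.hour >= 6), "usable"] = False
        res = daily_coverage(df, expected_per_day=24, min_fraction=0.5)
        assert (res.n_missing, res.n_total) == (1, 3)
        assert res.pct == pytest.approx(33.3)
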