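"""Treatment-level science products.

Builds on the hourly flux table: pre-treatment calibration coefficients
(Qc) aligning treatment groups, the warming effect Fe (% per °C) on
heterotrophic respiration, exponential (Q10) temperature-sensitivity
fits, cross-chamber coefficients of variation, aggregation of hourly
fluxes to daily/annual carbon sums, and missing-data accounting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    CARBON_G_PER_MOL,
    CalibrationSet,
    ChamberMeta,
    Q10Fit,
    WarmingEffect,
)

logger = logging.getLogger("chamberflux.analysis")

__all__ = [
    "calibrate_qc",
    "warming_effect",
    "fit_q10",
    "chamber_cv",
    "aggregate",
    "daily_coverage",
    "missing_fraction",
    "treatment_hourly_means",
    "GRAMS_C_PER_UMOL_HOUR",
]

#: 1 μmol CO2 m-2 s-1 sustained for one hour, as g C m-2.
GRAMS_C_PER_UMOL_HOUR = CARBON_G_PER_MOL * 3600.0 * 1e-6

_TRENCHED = ("trenched", "warmed_trenched")


def _usable(flux_df: pd.DataFrame) -> pd.DataFrame:
    df = flux_df
    if "usable" in df:
        df = df[df["usable"].astype(bool)]
    return df


def _window(df: pd.DataFrame, window: Optional[tuple] = None, col: str = "timestamp") -> pd.DataFrame:
    if window is None:
        return df
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return df[(df[col] >= lo) & (df[col] < hi)]


def treatment_hourly_means(
    flux_df: pd.DataFrame, value: str = "flux_umol_m2_s"
) -> pd.DataFrame:
    """Hour × treatment table of mean flux across that treatment's chambers."""
    df = _usable(flux_df).copy()
    df["hour"] = df["timestamp"].dt.floor("h")
    return df.pivot_table(index="hour", columns="treatment", values=value, aggfunc="mean")


def calibrate_qc(
    flux_df: pd.DataFrame,
    window: tuple,
    treatments: Sequence[str] = _TRENCHED,
    reference: Sequence[str] = _TRENCHED,
) -> CalibrationSet:
    """Pre-treatment calibration coefficients Qc per treatment.

    ``Qc(treatment)`` is the mean hourly flux over all reference chambers
    (by default both trenched groups, control excluded) divided by the
    mean hourly flux of the treatment's own chambers, both means taken
    over the paired hours present in both series.  The window must
    precede the warming onset for the coefficients to be meaningful.
    """
    df = _window(_usable(flux_df), window)
    if df.empty:
        raise ValueError(f"no usable fluxes in calibration window {window}")
    present = set(df["treatment"])
    absent = [t for t in treatments if t not in present]
    if absent:
        raise ValueError(f"treatments {absent} have no data in the calibration window")

    df = df.copy()
    df["hour"] = df["timestamp"].dt.floor("h")
    ref = (
        df[df["treatment"].isin(reference)]
        .groupby("hour")["flux_umol_m2_s"]
        .mean()
    )
    qc: dict[str, float] = {}
    n_hours: dict[str, int] = {}
    for tr in treatments:
        own = df[df["treatment"] == tr].groupby("hour")["flux_umol_m2_s"].mean()
        paired = ref.index.intersection(own.index)
        if len(paired) == 0:
            raise ValueError(f"no paired hours for treatment {tr!r} in the window")
        qc[tr] = float(ref.loc[paired].mean() / own.loc[paired].mean())
        n_hours[tr] = len(paired)
    logger.info("calibration window %s: Qc=%s", window, qc)
    return CalibrationSet(qc=qc, window=(pd.Timestamp(window[0]), pd.Timestamp(window[1])), n_hours=n_hours)


def warming_effect(
    flux_df: pd.DataFrame,
    soil_temp_df: pd.DataFrame,
    calibration: CalibrationSet,
    meta: dict[int, ChamberMeta],
    period: tuple,
    mode: str = "period_mean",
) -> WarmingEffect:
    """Warming effect Fe on heterotrophic respiration, % per °C.

    ``Fe = (Qcw·mean(Rhw) − Qch·mean(Rh)) / (Qch·mean(Rh) · (Tsw − Tsh)) × 100``

    where the means are taken over paired hours of the period.  The
    default ``period_mean`` mode applies the formula once to period-mean
    quantities; ``hourly`` evaluates it per paired hour and averages,
    which weights hours equally rather than by flux.

    ``soil_temp_df`` carries per-chamber 5-cm soil temperature in columns
    (timestamp, chamber, t_soil_c), e.g. the environment records.
    """
    if mode not in ("period_mean", "hourly"):
        raise ValueError("mode must be 'period_mean' or 'hourly'")
    for tr in _TRENCHED:
        if tr not in calibration.qc:
            raise ValueError(f"calibration lacks Qc for {tr!r}")
    hourly = treatment_hourly_means(_window(flux_df, period))
    if not all(t in hourly.columns for t in _TRENCHED):
        raise ValueError("period lacks usable fluxes for both trenched treatments")
    hourly = hourly.dropna(subset=list(_TRENCHED))

    st = _window(soil_temp_df, period).copy()
    st["treatment"] = st["chamber"].map(lambda ch: meta[int(ch)].treatment)
    st["hour"] = st["timestamp"].dt.floor("h")
    temps = st.pivot_table(index="hour", columns="treatment", values="t_soil_c", aggfunc="mean")
    if not all(t in temps.columns for t in _TRENCHED):
        raise ValueError("period lacks soil temperatures for both trenched treatments")
    paired = hourly.index.intersection(temps.dropna(subset=list(_TRENCHED)).index)
    if len(paired) == 0:
        raise ValueError("no paired hours with both fluxes and temperatures")
    hourly, temps = hourly.loc[paired], temps.loc[paired]

    q_ch, q_cw = calibration.qc["trenched"], calibration.qc["warmed_trenched"]
    rh = q_ch * hourly["trenched"]
    rhw = q_cw * hourly["warmed_trenched"]
    dt = temps["warmed_trenched"] - temps["trenched"]

    if mode == "period_mean":
        dtm = float(dt.mean())
        if abs(dtm) < 1e-9:
            raise ValueError("mean soil-temperature difference ~ 0; Fe undefined")
        fe = float((rhw.mean() - rh.mean()) / (rh.mean() * dtm) * 100.0)
        delta = dtm
    else:
        ok = dt.abs() > 1e-9
        fe = float(((rhw[ok] - rh[ok]) / (rh[ok] * dt[ok]) * 100.0).mean())
        delta = float(dt[ok].mean())
    return WarmingEffect(
        fe_pct_per_c=fe,
        delta_t_c=delta,
        calibrated_mean={"trenched": float(rh.mean()), "warmed_trenched": float(rhw.mean())},
        period=(pd.Timestamp(period[0]), pd.Timestamp(period[1])),
        n_hours=len(paired),
        mode=mode,
    )


def fit_q10(
    flux: np.ndarray | pd.Series,
    t_soil: np.ndarray | pd.Series,
    t_ref: float = 10.0,
    min_span_c: float = 5.0,
    min_n: int = 30,
    method: str = "ols",
    window: Optional[tuple] = None,
) -> Q10Fit:
    """Exponential temperature-sensitivity fit on paired flux/temperature.

    Default is log-linear OLS, ``ln R = a + b·T`` with ``Q10 = exp(10 b)``
    and reference flux ``exp(a + b·T_ref)``; only positive fluxes enter
    the log fit (the excluded count is reported).  ``method='nls'`` fits
    ``R = R_ref · Q10^((T − T_ref)/10)`` by nonlinear least squares
    instead, seeded from the OLS solution.
    """
    f = np.asarray(flux, dtype=float)
    t = np.asarray(t_soil, dtype=float)
    if f.shape != t.shape:
        raise ValueError("flux and temperature series must be aligned")
    ok = np.isfinite(f) & np.isfinite(t)
    f, t = f[ok], t[ok]
    pos = f > 0
    n_excluded = int((~pos).sum())
    f, t = f[pos], t[pos]
    if len(f) < min_n:
        raise ValueError(f"too few points for a Q10 fit ({len(f)} < {min_n})")
    span = float(t.max() - t.min())
    if span < min_span_c:
        raise ValueError(
            f"temperature span {span:.2f} °C below minimum {min_span_c} °C; Q10 unidentifiable"
        )

    res = stats.linregress(t, np.log(f))
    a, b, se_b = res.intercept, res.slope, res.stderr
    r2 = res.rvalue ** 2
    method_used = "ols"
    if method == "nls":
        def model(tt, r_ref, q10):
            return r_ref * q10 ** ((tt - t_ref) / 10.0)

        p0 = (math.exp(a + b * t_ref), math.exp(10.0 * b))
        popt, pcov = optimize.curve_fit(model, t, f, p0=p0, maxfev=10000)
        r_ref, q10 = popt
        se_q10 = math.sqrt(pcov[1, 1])
        resid = f - model(t, *popt)
        ss = 1.0 - resid.var() / f.var() if f.var() > 0 else math.nan
        return Q10Fit(
            q10=float(q10), flux_ref=float(r_ref), t_ref=t_ref,
            slope=math.log(q10) / 10.0, intercept=math.log(r_ref) - math.log(q10) / 10.0 * t_ref,
            slope_se=se_q10 / (10.0 * q10), r2=float(ss), n=len(f),
            n_excluded=n_excluded, window=window, method="nls",
        )
    if math.exp(10.0 * b) <= 0:
        raise ValueError("degenerate Q10 fit")
    return Q10Fit(
        q10=float(math.exp(10.0 * b)),
        flux_ref=float(math.exp(a + b * t_ref)),
        t_ref=t_ref,
        slope=float(b),
        intercept=float(a),
        slope_se=float(se_b),
        r2=float(r2),
        n=len(f),
        n_excluded=n_excluded,
        window=window,
        method=method_used,
    )


@dataclass
class CVResult:
    """Mean cross-chamber coefficient of variation for one treatment."""

    mean_cv_pct: float
    n_hours: int
    n_skipped: int          # hours with near-zero mean or < 2 chambers
    chambers: tuple[int, ...]


def chamber_cv(
    flux_df: pd.DataFrame,
    treatment: str,
    period: Optional[tuple] = None,
    exclude: Iterable[int] = (),
    min_chambers: int = 2,
) -> CVResult:
    """Mean hourly cross-chamber CV (%) of flux within one treatment.

    Per hour, CV = 100 · sd / mean across chambers (sample sd); the
    result is the mean over hours.  ``exclude`` removes listed chambers,
    e.g. for hot-spot sensitivity analyses.  Hours with fewer than
    ``min_chambers`` chambers or near-zero mean are skipped and counted.
    """
    df = _window(_usable(flux_df), period)
    df = df[df["treatment"] == treatment]
    df = df[~df["chamber"].isin(set(exclude))]
    if df.empty:
        raise ValueError(f"no usable fluxes for treatment {treatment!r} in the period")
    df = df.copy()
    df["hour"] = df["timestamp"].dt.floor("h")
    g = df.groupby("hour")["flux_umol_m2_s"]
    stats_df = g.agg(["mean", "std", "count"])
    enough = stats_df["count"] >= min_chambers
    nonzero = stats_df["mean"].abs() > 1e-9
    ok = enough & nonzero
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("chamber_cv(%s): skipped %d hours", treatment, n_skipped)
    cv = 100.0 * stats_df.loc[ok, "std"] / stats_df.loc[ok, "mean"]
    return CVResult(
        mean_cv_pct=float(cv.mean()),
        n_hours=int(ok.sum()),
        n_skipped=n_skipped,
        chambers=tuple(sorted(set(df["chamber"].astype(int)))),
    )


@dataclass
class AggregateResult:
    """Daily and annualised carbon sums from an hourly flux series."""

    daily: pd.DataFrame          # date, g_c_m2, n_hours, n_filled
    total_g_c_m2: float
    total_t_c_ha: float
    annual_g_c_m2: float         # total scaled to 365 days
    annual_t_c_ha: float
    fill_fraction: float
    n_hours: int
    n_filled: int


def aggregate(
    hourly_flux: pd.Series,
    q10_fit: Optional[Q10Fit] = None,
    t_soil: Optional[pd.Series] = None,
) -> AggregateResult:
    """Integrate an hourly flux series (μmol m-2 s-1) to carbon sums.

    Each hour contributes ``flux · 3600 · 12.011e-6`` g C m-2; daily sums
    add up exactly to the total (conservation).  Missing hours are either
    left out or, when a Q10 fit and a soil-temperature series are
    supplied, filled from the fitted temperature response; the filled
    fraction is reported.  The annualised figures scale the period total
    to 365 days.
    """
    s = hourly_flux.copy()
    if not isinstance(s.index, pd.DatetimeIndex):
        raise ValueError("hourly flux series must have a datetime index")
    full = pd.date_range(s.index.min().floor("D"), s.index.max().ceil("D"), freq="h", inclusive="left")
    s = s.reindex(full)
    missing = s.isna()
    n_filled = 0
    if missing.any() and q10_fit is not None:
        if t_soil is None:
            raise ValueError("gap filling requested but no soil-temperature series supplied")
        t = t_soil.reindex(full)
        fillable = missing & t.notna()
        s[fillable] = q10_fit.predict(t[fillable].to_numpy())
        n_filled = int(fillable.sum())
    elif missing.any() and q10_fit is None and t_soil is not None:
        raise ValueError("soil temperatures supplied without a Q10 fit; pass both for gap filling")

    hourly_gc = s * GRAMS_C_PER_UMOL_HOUR
    by_day = hourly_gc.groupby(hourly_gc.index.floor("D"))
    daily = pd.DataFrame(
        {
            "g_c_m2": by_day.sum(min_count=1),
            "n_hours": by_day.count(),
        }
    )
    daily.index.name = "date"
    daily = daily.reset_index()
    total = float(np.nansum(daily["g_c_m2"].to_numpy()))
    n_hours = int(s.notna().sum())
    days_covered = n_hours / 24.0
    annual = total * (365.0 / days_covered) if days_covered > 0 else math.nan
    return AggregateResult(
        daily=daily,
        total_g_c_m2=total,
        total_t_c_ha=total * 0.01,
        annual_g_c_m2=annual,
        annual_t_c_ha=annual * 0.01,
        fill_fraction=n_filled / len(full) if len(full) else 0.0,
        n_hours=n_hours,
        n_filled=n_filled,
    )


@dataclass
class MissingSummary:
    n_missing: int
    n_total: int
    pct: float                   # to one decimal


def missing_fraction(n_missing: int, n_total: int) -> MissingSummary:
    """Missing-day accounting: counts and percentage to one decimal."""
    if n_total <= 0:
        raise ValueError("total day count must be positive")
    return MissingSummary(
        n_missing=n_missing,
        n_total=n_total,
        pct=round(100.0 * n_missing / n_total, 1),
    )


def daily_coverage(
    flux_df: pd.DataFrame,
    expected_per_day: int,
    min_fraction: float = 0.5,
    period: Optional[tuple] = None,
) -> MissingSummary:
    """Classify days as missing when fewer than ``min_fraction`` of the
    expected closures are usable, and summarise."""
    df = _window(flux_df, period)
    if df.empty:
        raise ValueError("no flux records in the period")
    usable = df.copy()
    usable["day"] = usable["timestamp"].dt.floor("D")
    counts = usable[usable["usable"].astype(bool)].groupby("day").size()
    first, last = df["timestamp"].min().floor("D"), df["timestamp"].max().floor("D")
    all_days = pd.date_range(first, last, freq="D")
    counts = counts.reindex(all_days, fill_value=0)
    n_missing = int((counts < min_fraction * expected_per_day).sum())
    return missing_fraction(n_missing, len(all_days))
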