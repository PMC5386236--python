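"""Synthetic campaign generator emulating a multichannel automated chamber system.

The generator emulates a 15-chamber flow-through, non-steady-state system
on a warm-temperate forest floor: every hour the chambers close
sequentially for 240 s each, the datalogger stores 10-s-averaged CO2,
flow, pressure and temperature records, and a separate logger stores
half-hourly soil temperature and moisture.  True effluxes follow an
exponential (Q10) temperature response with treatment-specific baselines,
multiplicative per-chamber spatial offsets ("hot spots"), and an optional
warming multiplier for warmed-trenched plots.  Concentration ramps are
built by inverting the simplified closed-chamber flux equation, so that
processing noise-free records through the flux module returns the true
efflux to floating precision.

Everything is driven by one seeded generator: identical configuration and
seed give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    CELSIUS_TO_K,
    ChamberMeta,
    ClosureSegment,
    FaultSpec,
    TruthBundle,
    default_chamber_meta,
    flux_coefficient,
)

__all__ = [
    "SiteForcing",
    "TrueFluxModel",
    "InstrumentModel",
    "CampaignResult",
    "simulate_campaign",
    "inject_fault",
    "air_temperature",
    "soil_temperature",
    "hourly_truth",
    "make_segment",
    "ScheduleError",
]


class ScheduleError(ValueError):
    """Raised when the closure schedule cannot fit into the measurement cycle."""


# day-of-year anchors for the two printed monthly means (mid-January,
# mid-August); the seasonal sinusoid peaks at the August anchor.
_DOY_JAN, _DOY_AUG = 15.0, 227.0
_YEAR_DAYS = 365.25


@dataclass
class SiteForcing:
    """Seasonal + diel meteorological forcing for the simulated site.

    The seasonal cycle is a single sinusoid solved to pass exactly through
    the site's coldest and warmest monthly means (7.0 °C in January,
    27.9 °C in August by default), peaking in mid-August.  A diel sinusoid
    (afternoon maximum) is superimposed; the 5-cm soil temperature follows
    the air temperature with a damped, lagged diel component.  Soil
    moisture is a base level plus exponentially decaying rain-event pulses.
    """

    t_jan_c: float = 7.0             # coldest monthly mean, °C
    t_aug_c: float = 27.9            # warmest monthly mean, °C
    diel_amplitude_c: float = 3.0    # air diel half-range, °C
    soil_diel_factor: float = 0.5    # diel damping at 5 cm depth
    soil_diel_lag_h: float = 2.0     # diel phase lag at 5 cm, h
    moisture_base: float = 0.30      # volumetric fraction, m3 m-3
    rain_events_per_day: float = 0.35
    rain_boost_max: float = 0.10     # max moisture jump per event
    moisture_decay_days: float = 5.0
    warming_offset_c: float = 2.5    # soil warming at 5 cm in warmed plots

    def seasonal_params(self) -> tuple[float, float]:
        """(annual mean, amplitude) of the seasonal sinusoid."""
        c = np.cos(2 * np.pi * (_DOY_JAN - _DOY_AUG) / _YEAR_DAYS)
        amp = (self.t_aug_c - self.t_jan_c) / (1.0 - c)
        return self.t_aug_c - amp, amp


def _fractional_doy(times: pd.DatetimeIndex) -> np.ndarray:
    return times.dayofyear.to_numpy(dtype=float) + times.hour.to_numpy() / 24.0


def _seasonal(times: pd.DatetimeIndex, forcing: SiteForcing) -> np.ndarray:
    mean, amp = forcing.seasonal_params()
    doy = _fractional_doy(times)
    return mean + amp * np.cos(2 * np.pi * (doy - _DOY_AUG) / _YEAR_DAYS)


def air_temperature(times: pd.DatetimeIndex, forcing: SiteForcing) -> np.ndarray:
    """Chamber-height air temperature (°C) at ``times``."""
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    diel = forcing.diel_amplitude_c * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
    return _seasonal(times, forcing) + diel


def soil_temperature(
    times: pd.DatetimeIndex, forcing: SiteForcing, warmed: bool = False
) -> np.ndarray:
    """5-cm soil temperature (°C); ``warmed`` adds the warming offset."""
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    diel = (
        forcing.soil_diel_factor
        * forcing.diel_amplitude_c
        * np.cos(2 * np.pi * (hour - 14.0 - forcing.soil_diel_lag_h) / 24.0)
    )
    t = _seasonal(times, forcing) + diel
    if warmed:
        t = t + forcing.warming_offset_c
    return t


def _soil_moisture(
    times: pd.DatetimeIndex, forcing: SiteForcing, rng: np.random.Generator
) -> np.ndarray:
    """Base moisture plus seeded rain-event pulses with exponential decay."""
    t0 = times[0]
    days = (times[-1] - t0).total_seconds() / 86400.0
    n_events = rng.poisson(forcing.rain_events_per_day * max(days, 1.0))
    event_t = np.sort(rng.uniform(0.0, max(days, 1.0), n_events))
    boosts = rng.uniform(0.2 * forcing.rain_boost_max, forcing.rain_boost_max, n_events)
    tdays = (times - t0).total_seconds().to_numpy() / 86400.0
    vwc = np.full(len(times), forcing.moisture_base)
    for te, b in zip(event_t, boosts):
        dt = tdays - te
        vwc += np.where(dt >= 0, b * np.exp(-dt / forcing.moisture_decay_days), 0.0)
    return np.clip(vwc, 0.0, 0.6)


@dataclass
class TrueFluxModel:
    """Ground-truth efflux model.

    Flux for chamber *c* at time *t*:

        R(c, t) = base(treatment) * offset_c * Q10^((Ts(t) - T_ref)/10) * warm(t)

    where ``Ts`` is the *unwarmed* 5-cm soil temperature and, for
    warmed-trenched chambers after the warming onset,
    ``warm(t) = 1 + Fe * ΔT / 100`` with ΔT the configured warming offset.
    Expressing the warming response through Fe (percent increase per °C of
    warming) keeps it an independent dial rather than a consequence of Q10.
    """

    flux_ref: float = 2.0            # control baseline at t_ref, μmol m-2 s-1
    q10: float = 2.5
    t_ref: float = 10.0              # °C
    trenched_fraction: float = 0.75  # Rh baseline relative to control
    fe_pct_per_c: float = 9.4        # warming effect, % per °C
    offset_sd: float = 0.2           # lognormal sd of per-chamber spatial offsets
    hot_spot_chamber: Optional[int] = None
    hot_spot_multiplier: float = 2.5
    moisture_sensitivity: float = 0.0  # optional multiplicative modifier, off by default

    def __post_init__(self) -> None:
        if self.q10 <= 0:
            raise ValueError("Q10 must be positive")
        if self.flux_ref <= 0 or self.trenched_fraction <= 0:
            raise ValueError("baseline fluxes must be positive")

    def baseline(self, treatment: str) -> float:
        return self.flux_ref if treatment == "control" else self.flux_ref * self.trenched_fraction

    def temperature_response(self, t_soil_c: np.ndarray | float) -> np.ndarray | float:
        return self.q10 ** ((np.asarray(t_soil_c, dtype=float) - self.t_ref) / 10.0)


@dataclass
class InstrumentModel:
    """Measurement-system description: schedule, noise, geometry, faults."""

    n_chambers: int = 15
    closure_s: int = 240             # lid closed per chamber per cycle
    record_interval_s: int = 10
    cycle_s: int = 3600
    dead_band_records: int = 3       # initial records contaminated by tubing lag
    co2_noise_sd: float = 0.5        # ppm, i.i.d. Gaussian on each 10-s record
    ambient_co2: float = 400.0       # ppm baseline at lid closure
    p_air_kpa: float = 99.8          # chamber-height ambient pressure (site ~130 m asl)
    cell_pressure_offset_kpa: float = 5.0  # IRGA cell runs above ambient
    flow_lpm: float = 5.0
    flow_noise_sd: float = 0.05
    spike_rate: float = 0.001        # per-record probability of an electrical spike
    spike_ppm: tuple[float, float] = (10.0, 20.0)
    faults: list[FaultSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_chambers < 1:
            raise ScheduleError("need at least one chamber")
        if self.n_chambers * self.closure_s > self.cycle_s:
            raise ScheduleError(
                f"{self.n_chambers} closures of {self.closure_s}s exceed the "
                f"{self.cycle_s}s cycle"
            )
        if self.closure_s % self.record_interval_s:
            raise ScheduleError("closure length must be a multiple of the record interval")

    @property
    def records_per_closure(self) -> int:
        return self.closure_s // self.record_interval_s

    def duty_cycle(self) -> dict[str, float]:
        """Per-chamber open/closed minutes per cycle and the open fraction."""
        closed_min = self.closure_s / 60.0
        cycle_min = self.cycle_s / 60.0
        return {
            "closed_min_per_cycle": closed_min,
            "open_min_per_cycle": cycle_min - closed_min,
            "open_fraction": (cycle_min - closed_min) / cycle_min,
        }


@dataclass
class CampaignResult:
    raw: pd.DataFrame
    env: pd.DataFrame
    truth: TruthBundle


def _pressure(times: pd.DatetimeIndex, instrument: InstrumentModel) -> np.ndarray:
    # slow synoptic-scale wobble around the site mean
    doy = _fractional_doy(times)
    return instrument.p_air_kpa + 0.4 * np.sin(2 * np.pi * doy / 6.1)


def simulate_campaign(
    forcing: SiteForcing,
    fluxmodel: TrueFluxModel,
    instrument: InstrumentModel,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
    seed: int,
    meta: Optional[dict[int, ChamberMeta]] = None,
    warming_start: Optional[str | pd.Timestamp] = None,
) -> CampaignResult:
    """Generate raw efflux records, environment records and ground truth.

    Parameters
    ----------
    start, end
        Campaign period, ``[start, end)``, at least one day.
    seed
        Seeds every random draw; identical configuration and seed give
        identical output.
    meta
        Chamber -> metadata map; defaults to three equal treatment groups.
    warming_start
        Onset of the soil-warming manipulation; defaults to 18 days after
        ``start`` (an initial pre-treatment window for calibration).
    """
    instrument.validate()
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end - start < pd.Timedelta(days=1):
        raise ValueError("campaign period must span at least one day")
    if warming_start is None:
        warming_start = start + pd.Timedelta(days=18)
    else:
        warming_start = pd.Timestamp(warming_start)
    if meta is None:
        meta = default_chamber_meta(instrument.n_chambers)
    chambers = sorted(meta)
    if len(chambers) > instrument.n_chambers:
        raise ScheduleError("more chambers in meta than the schedule allows")

    rng = np.random.default_rng(seed)

    # per-chamber multiplicative spatial offsets (lognormal, optional hot spot)
    offsets = {
        ch: float(np.exp(rng.normal(0.0, fluxmodel.offset_sd))) for ch in chambers
    }
    if fluxmodel.hot_spot_chamber is not None:
        offsets[fluxmodel.hot_spot_chamber] = (
            offsets.get(fluxmodel.hot_spot_chamber, 1.0) * fluxmodel.hot_spot_multiplier
        )

    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n_rec = instrument.records_per_closure
    rec_off = np.arange(n_rec) * instrument.record_interval_s  # s within closure
    lag_s = instrument.dead_band_records * instrument.record_interval_s

    env_times = pd.date_range(start, end, freq="30min", inclusive="left")
    vwc_base = _soil_moisture(env_times, forcing, rng)

    raw_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    spike_rows: list[dict] = []
    env_cols: dict[int, np.ndarray] = {}
    vwc_cols: dict[int, np.ndarray] = {}

    for slot, ch in enumerate(chambers):
        m = meta[ch]
        closure_starts = hours + pd.Timedelta(seconds=slot * instrument.closure_s)
        t_air = air_temperature(closure_starts, forcing)
        ts_unwarmed = soil_temperature(closure_starts, forcing, warmed=False)
        warmed = m.treatment == "warmed_trenched"
        active = np.asarray(closure_starts >= warming_start) if warmed else np.zeros(len(hours), bool)
        ts_rec = ts_unwarmed + forcing.warming_offset_c * active
        p_air = _pressure(closure_starts, instrument)

        r_true = (
            fluxmodel.baseline(m.treatment)
            * offsets[ch]
            * np.asarray(fluxmodel.temperature_response(ts_unwarmed))
        )
        r_true = r_true * (1.0 + fluxmodel.fe_pct_per_c * forcing.warming_offset_c / 100.0 * active)
        if fluxmodel.moisture_sensitivity:
            vwc_h = np.interp(
                (closure_starts - start).total_seconds().to_numpy(),
                (env_times - start).total_seconds().to_numpy(),
                vwc_base,
            )
            r_true = r_true * (1.0 + fluxmodel.moisture_sensitivity * (vwc_h - forcing.moisture_base))

        # concentration ramp from the inverse of the simplified flux equation
        slope = r_true * (t_air + CELSIUS_TO_K) / (flux_coefficient(m.vs_ratio) * p_air)

        co2 = instrument.ambient_co2 + slope[:, None] * (rec_off[None, :] - lag_s)
        if instrument.dead_band_records:
            k = instrument.dead_band_records
            # stale tube/headspace air near ambient before the ramp reaches the IRGA
            co2[:, :k] = instrument.ambient_co2 + rng.normal(0.0, 1.0, (len(hours), k))
        if instrument.co2_noise_sd > 0:
            co2 = co2 + rng.normal(0.0, instrument.co2_noise_sd, co2.shape)
        if instrument.spike_rate > 0:
            hit = rng.random(co2.shape) < instrument.spike_rate
            n_hit = int(hit.sum())
            if n_hit:
                mag = rng.uniform(*instrument.spike_ppm, n_hit) * rng.choice([-1.0, 1.0], n_hit)
                co2[hit] += mag
                hi, ri = np.nonzero(hit)
                for h, r_i, mg in zip(hi, ri, mag):
                    spike_rows.append(
                        {
                            "chamber": ch,
                            "timestamp": closure_starts[h] + pd.Timedelta(seconds=int(rec_off[r_i])),
                            "magnitude_ppm": float(mg),
                        }
                    )

        flow = np.full(co2.shape, instrument.flow_lpm)
        if instrument.flow_noise_sd > 0:
            flow = flow + rng.normal(0.0, instrument.flow_noise_sd, co2.shape)

        stamps = (
            closure_starts.values[:, None] + rec_off[None, :] * np.timedelta64(1, "s")
        ).ravel()
        raw_frames.append(
            pd.DataFrame(
                {
                    "timestamp": stamps,
                    "chamber": ch,
                    "co2_ppm": co2.ravel(),
                    "flow_lpm": flow.ravel(),
                    "p_air_kpa": np.repeat(p_air, n_rec),
                    "p_cell_kpa": np.repeat(p_air + instrument.cell_pressure_offset_kpa, n_rec),
                    "t_air_c": np.repeat(t_air, n_rec),
                    "t_soil_c": np.repeat(ts_rec, n_rec),
                }
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "chamber": ch,
                    "timestamp": closure_starts,
                    "true_flux": r_true,
                    "t_soil": ts_rec,
                    "t_soil_unwarmed": ts_unwarmed,
                    "treatment": m.treatment,
                }
            )
        )

        env_warm = np.asarray(env_times >= warming_start) if warmed else np.zeros(len(env_times), bool)
        env_cols[ch] = soil_temperature(env_times, forcing, warmed=False) + forcing.warming_offset_c * env_warm
        vwc_cols[ch] = np.clip(vwc_base + rng.normal(0.0, 0.01), 0.0, 0.6)

    raw = pd.concat(raw_frames, ignore_index=True)
    raw = raw.sort_values("timestamp", kind="mergesort", ignore_index=True)

    truth_flux = pd.concat(truth_frames, ignore_index=True)
    truth_flux = truth_flux.sort_values(["timestamp", "chamber"], kind="mergesort", ignore_index=True)

    env = pd.concat(
        [
            pd.DataFrame(
                {
                    "timestamp": env_times,
                    "chamber": ch,
                    "t_soil_c": env_cols[ch],
                    "vwc": vwc_cols[ch],
                    "t_air_amb_c": air_temperature(env_times, forcing),
                    "rh": np.clip(
                        60.0
                        + 60.0 * (vwc_base - forcing.moisture_base)
                        + 8.0 * np.cos(2 * np.pi * (env_times.hour.to_numpy() - 4.0) / 24.0),
                        30.0,
                        100.0,
                    ),
                }
            )
            for ch in chambers
        ],
        ignore_index=True,
    ).sort_values(["timestamp", "chamber"], kind="mergesort", ignore_index=True)

    spikes = pd.DataFrame(spike_rows, columns=["chamber", "timestamp", "magnitude_ppm"])
    truth = TruthBundle(
        flux=truth_flux,
        q10=fluxmodel.q10,
        fe_pct_per_c=fluxmodel.fe_pct_per_c,
        warming_offset_c=forcing.warming_offset_c,
        chamber_offsets=offsets,
        warming_start=warming_start,
        faults=[],
        spikes=spikes,
    )

    for spec in instrument.faults:
        raw = inject_fault(raw, spec, instrument, rng=rng, truth=truth)

    return CampaignResult(raw=raw, env=env, truth=truth)


def inject_fault(
    raw: pd.DataFrame,
    spec: FaultSpec,
    instrument: InstrumentModel,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[TruthBundle] = None,
) -> pd.DataFrame:
    """Apply one instrument fault to generated raw records.

    Fault phenomenology follows what faulty closures look like on this
    kind of system: a pump stoppage freezes the IRGA reading near its last
    value before it decays toward ambient while the measured flow drops to
    ~0; a lid leak attenuates the ramp with a concave saturating shape
    (zero attenuation is the identity); a stopped mixing fan inflates
    record-to-record scatter.  The fault is logged in ``truth`` when given.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = raw.copy()
    sel = (
        (out["chamber"] == spec.chamber)
        & (out["timestamp"] >= spec.start)
        & (out["timestamp"] < spec.end)
    )
    idx = out.index[sel]
    if len(idx):
        cycle = pd.Timedelta(seconds=instrument.cycle_s)
        groups = out.loc[idx, "timestamp"].dt.floor(cycle)
        for _, gidx in out.loc[idx].groupby(groups).groups.items():
            gidx = np.asarray(gidx)
            t0 = out.loc[gidx[0], "timestamp"]
            o = (out.loc[gidx, "timestamp"] - t0).dt.total_seconds().to_numpy()
            c = out.loc[gidx, "co2_ppm"].to_numpy()
            amb = instrument.ambient_co2
            if spec.kind == "pump_stop":
                span = o[-1] if o[-1] > 0 else 1.0
                t_p = spec.pump_plateau_frac * span
                hold = c[0]
                decay = np.where(
                    o < t_p,
                    0.0,
                    spec.pump_decay_ppm * (1.0 - np.exp(-(o - t_p) / spec.pump_decay_tau_s)),
                )
                newc = hold - decay + rng.normal(0.0, max(instrument.co2_noise_sd, 0.3), len(o))
                out.loc[gidx, "co2_ppm"] = newc
                out.loc[gidx, "flow_lpm"] = np.clip(
                    rng.normal(0.05, 0.02, len(o)), 0.0, None
                )
            elif spec.kind == "leak":
                a = spec.leak_attenuation
                tau = 100.0
                with np.errstate(divide="ignore", invalid="ignore"):
                    sat = np.where(o > 0, tau * (1.0 - np.exp(-o / tau)) / np.where(o > 0, o, 1.0), 1.0)
                out.loc[gidx, "co2_ppm"] = amb + (c - amb) * ((1.0 - a) + a * sat)
            elif spec.kind == "fan":
                extra = spec.fan_noise_factor * max(instrument.co2_noise_sd, 0.3)
                out.loc[gidx, "co2_ppm"] = c + rng.normal(0.0, extra, len(o))
    if truth is not None:
        truth.faults.append(spec)
    return out


def hourly_truth(
    forcing: SiteForcing,
    fluxmodel: TrueFluxModel,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
    treatment: str = "control",
    chamber_offset: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Hourly noise-free (or lognormally perturbed) true flux series.

    A light-weight path for desk-scale simulation studies (e.g. Q10
    parameter recovery) that do not need record-level instrument emulation.
    Multiplicative noise is lognormal: ``flux * exp(N(0, noise_sd))``.
    """
    times = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="h", inclusive="left")
    ts = soil_temperature(times, forcing, warmed=False)
    flux = fluxmodel.baseline(treatment) * chamber_offset * np.asarray(
        fluxmodel.temperature_response(ts)
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flux = flux * np.exp(rng.normal(0.0, noise_sd, len(flux)))
    return pd.DataFrame({"timestamp": times, "t_soil": ts, "flux": flux})


def make_segment(
    slope: float,
    n: int = 24,
    interval_s: float = 10.0,
    c0: float = 400.0,
    noise_sd: float = 0.0,
    p_air: float = 101.32,
    t_air: float = 25.0,
    t_soil: float = 15.0,
    chamber: int = 1,
    start: str | pd.Timestamp = "2009-07-01 00:00:00",
    w0: Optional[float] = None,
    w_ramp: float = 0.0,
    seed: Optional[int] = None,
    treatment: str = "control",
) -> ClosureSegment:
    """Build a single synthetic closure segment — a convenience for tests
    and worked examples.  ``slope`` is the CO2 ramp in ppm s-1; an optional
    water-vapour ramp ``w_ramp`` (mmol mol-1 s-1) from ``w0`` supports the
    full dilution-corrected flux equation."""
    offs = np.arange(n) * interval_s
    co2 = c0 + slope * offs
    if noise_sd > 0:
        co2 = co2 + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    w = None if w0 is None else w0 + w_ramp * offs
    const = lambda v: np.full(n, float(v))
    return ClosureSegment(
        chamber=chamber,
        start=pd.Timestamp(start),
        offsets=offs.astype(float),
        co2=co2,
        flow=const(5.0),
        p_air=const(p_air),
        t_air=const(t_air),
        t_soil=const(t_soil),
        p_cell=const(p_air + 5.0),
        w=w,
        treatment=treatment,
    )
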