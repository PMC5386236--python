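"""Per-closure soil CO2 efflux computation.

Three estimators are provided for the non-steady-state closed-chamber
method.  With concentrations in μmol mol-1 (ppm), chamber-height pressure
``P_air`` in kPa, air temperature in °C and the chamber coefficient
``k = 1000 (V/S) / R`` (= 60.14 for V/S = 0.5 m):

* *linear model* — ``Rs = k · P_air / (T_air + 273.15) · slope`` where
  ``slope`` is the OLS slope of CO2 against closure time;
* *average model* — same, with the slope term replaced by the mean of the
  per-interval concentration changes ΔC/Δt over retained record pairs;
* *full model* — the dilution-corrected form using pressure in Pa and a
  water-vapour mole-fraction series W (mmol mol-1):
  ``Rs = P0 (V/S) / (R (T_air+273.15)) · (∂C/∂t + C/(1000−W) · ∂W/∂t)``,
  which reduces exactly to the linear model when ∂W/∂t = 0.

``P_air`` must be the chamber-height ambient pressure, never the IRGA
cell pressure — the cell typically runs ~5 kPa above ambient, which would
bias the flux by several percent.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .qc import QCParams, _ols, run_qc
from .types import (
    CELSIUS_TO_K,
    R_GAS,
    ChamberMeta,
    ClosureSegment,
    FluxRecord,
    QCResult,
    flux_coefficient,
)

logger = logging.getLogger("chamberflux.flux")

__all__ = ["flux_linear", "flux_average", "flux_full", "process_segments", "compute_fluxes"]


def _ambient_conditions(
    segment: ClosureSegment,
    qc: QCResult,
    pressure_fallback_kpa: Optional[float],
    t_air_fallback_c: Optional[float],
) -> tuple[float, float, str, list[str]]:
    """Mean chamber pressure/temperature over retained records, with fallbacks."""
    idx = qc.retained
    flags: list[str] = []

    def _nanmean(values: np.ndarray) -> float:
        values = values[np.isfinite(values)]
        return float(values.mean()) if len(values) else math.nan

    p = _nanmean(segment.p_air[idx]) if len(idx) else math.nan
    if not math.isfinite(p):
        if pressure_fallback_kpa is None:
            raise ValueError(
                f"closure {segment.chamber}@{segment.start}: no chamber pressure and "
                "no pressure fallback configured"
            )
        p = pressure_fallback_kpa
        flags.append("pressure_fallback")
        logger.info("closure %s@%s: using fallback pressure", segment.chamber, segment.start)
    t = _nanmean(segment.t_air[idx]) if len(idx) else math.nan
    source = "chamber"
    if not math.isfinite(t):
        if t_air_fallback_c is None or not math.isfinite(t_air_fallback_c):
            flags.append("no_temperature")
            return p, math.nan, "none", flags
        t, source = t_air_fallback_c, "site"
        flags.append("t_air_site")
    return p, t, source, flags


def _record(
    segment: ClosureSegment,
    qc: QCResult,
    flux: float,
    model: str,
    p: float,
    t: float,
    source: str,
    flags: list[str],
) -> FluxRecord:
    return FluxRecord(
        chamber=segment.chamber,
        start=segment.start,
        flux=flux,
        model=model,
        p_air_kpa=p,
        t_air_c=t,
        t_air_source=source,
        r=qc.r,
        n_used=qc.n_used,
        usable=qc.usable,
        treatment=segment.treatment,
        flags=list(qc.flags) + flags,
    )


def flux_linear(
    segment: ClosureSegment,
    qc: QCResult,
    meta: Optional[ChamberMeta] = None,
    vs_ratio: Optional[float] = None,
    pressure_fallback_kpa: Optional[float] = None,
    t_air_fallback_c: Optional[float] = None,
) -> FluxRecord:
    """Efflux from the final QC linear-fit slope (μmol m-2 s-1)."""
    vs = vs_ratio if vs_ratio is not None else (meta.vs_ratio if meta else 0.5)
    p, t, source, flags = _ambient_conditions(segment, qc, pressure_fallback_kpa, t_air_fallback_c)
    flux = flux_coefficient(vs) * p / (t + CELSIUS_TO_K) * qc.slope
    return _record(segment, qc, flux, "linear", p, t, source, flags)


def flux_average(
    segment: ClosureSegment,
    qc: QCResult,
    meta: Optional[ChamberMeta] = None,
    vs_ratio: Optional[float] = None,
    pressure_fallback_kpa: Optional[float] = None,
    t_air_fallback_c: Optional[float] = None,
    literal_n: bool = False,
) -> FluxRecord:
    """Efflux from the mean of per-interval concentration changes.

    Slopes use the actual spacing of retained records, so gaps left by
    outlier removal are handled correctly.  ``literal_n`` divides the sum
    of the n−1 interval slopes by n instead of n−1 (a non-standard
    normalisation retained as an option).
    """
    idx = qc.retained
    if len(idx) < 2:
        raise ValueError("average model needs at least two retained records")
    t_off = np.asarray(segment.offsets, dtype=float)[idx]
    c = np.asarray(segment.co2, dtype=float)[idx]
    dcdt = np.diff(c) / np.diff(t_off)
    slope = dcdt.sum() / (len(dcdt) + 1) if literal_n else dcdt.mean()
    vs = vs_ratio if vs_ratio is not None else (meta.vs_ratio if meta else 0.5)
    p, t, source, flags = _ambient_conditions(segment, qc, pressure_fallback_kpa, t_air_fallback_c)
    flux = flux_coefficient(vs) * p / (t + CELSIUS_TO_K) * slope
    return _record(segment, qc, flux, "average", p, t, source, flags)


def flux_full(
    segment: ClosureSegment,
    qc: QCResult,
    meta: Optional[ChamberMeta] = None,
    vs_ratio: Optional[float] = None,
    pressure_fallback_kpa: Optional[float] = None,
    t_air_fallback_c: Optional[float] = None,
) -> FluxRecord:
    """Dilution-corrected efflux using the closure's water-vapour series.

    Requires ``segment.w`` (mmol H2O mol-1); with a constant W series the
    result equals the linear model exactly.
    """
    if segment.w is None:
        raise ValueError("full model requires a water-vapour series on the segment")
    idx = qc.retained
    w = np.asarray(segment.w, dtype=float)[idx]
    if np.any(w >= 1000.0) or np.any(w < 0.0):
        raise ValueError("water-vapour mole fraction must lie in [0, 1000) mmol mol-1")
    t_off = np.asarray(segment.offsets, dtype=float)[idx]
    c = np.asarray(segment.co2, dtype=float)[idx]
    slope_w, *_ = _ols(t_off, w)
    cbar, wbar = float(c.mean()), float(w.mean())
    vs = vs_ratio if vs_ratio is not None else (meta.vs_ratio if meta else 0.5)
    p, t, source, flags = _ambient_conditions(segment, qc, pressure_fallback_kpa, t_air_fallback_c)
    p0 = p * 1000.0  # Pa
    term = qc.slope + cbar / (1000.0 - wbar) * slope_w
    flux = p0 * vs / (R_GAS * (t + CELSIUS_TO_K)) * term
    return _record(segment, qc, flux, "full", p, t, source, flags)


_MODELS = {"linear": flux_linear, "average": flux_average, "full": flux_full}


def process_segments(
    segments: Iterable[ClosureSegment],
    qc_params: QCParams = QCParams(),
    model: str = "linear",
    meta: Optional[dict[int, ChamberMeta]] = None,
    pressure_fallback_kpa: Optional[float] = None,
    t_air_fallback_c: Optional[float] = None,
) -> tuple[list[FluxRecord], dict[str, int]]:
    """Screen and compute efflux for a sequence of closures.

    Returns the flux records (one per non-degenerate closure, usable or
    not) and a QC summary counting records in/out per rejection reason.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODELS)}")
    fn = _MODELS[model]
    records: list[FluxRecord] = []
    summary: dict[str, int] = {"closures": 0, "usable": 0, "records_in": 0, "records_kept": 0}
    for seg in segments:
        summary["closures"] += 1
        summary["records_in"] += seg.n
        qc = run_qc(seg, qc_params)
        summary["records_kept"] += qc.n_used
        for reason, idxs in qc.rejected.items():
            summary[reason] = summary.get(reason, 0) + len(idxs)
        if qc.n_used < 2 or not math.isfinite(qc.slope):
            summary["degenerate"] = summary.get("degenerate", 0) + 1
            continue
        m = meta.get(seg.chamber) if meta else None
        rec = fn(
            seg,
            qc,
            meta=m,
            pressure_fallback_kpa=pressure_fallback_kpa,
            t_air_fallback_c=t_air_fallback_c,
        )
        records.append(rec)
        if rec.usable:
            summary["usable"] += 1
    logger.info(
        "processed %d closures (%d usable): %s",
        summary["closures"], summary["usable"],
        {k: v for k, v in summary.items() if k.startswith(("dead", "outlier", "short"))},
    )
    return records, summary


def compute_fluxes(
    raw: pd.DataFrame,
    meta: dict[int, ChamberMeta],
    qc_params: QCParams = QCParams(),
    model: str = "linear",
    record_interval_s: float = 10.0,
    cycle_s: int = 3600,
    pressure_fallback_kpa: Optional[float] = None,
    t_air_fallback_c: Optional[float] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Raw records -> tidy flux table (segmentation + QC + flux in one call)."""
    from .io import flux_frame, segment_closures

    segments = segment_closures(
        raw, meta, record_interval_s=record_interval_s, cycle_s=cycle_s
    )
    records, summary = process_segments(
        segments,
        qc_params=qc_params,
        model=model,
        meta=meta,
        pressure_fallback_kpa=pressure_fallback_kpa,
        t_air_fallback_c=t_air_fallback_c,
    )
    return flux_frame(records), summary
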