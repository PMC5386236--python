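"""Readers, writers and closure segmentation for the chamberflux dialects.

Three comma-delimited, versioned dialects are defined (raw efflux records,
half-hourly environment records, processed flux tables).  Each file opens
with a ``# chamberflux <kind> v1`` comment line followed by a header row;
timestamps are ISO-8601 at local standard time (no DST) and missing values
use a configurable sentinel (default ``NA``).  Files from other
dataloggers are supported by supplying a column map in the dialect —
nothing is hard-coded to the synthetic writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ChamberMeta, ClosureSegment, FluxRecord

logger = logging.getLogger("chamberflux.io")

RAW_COLUMNS = [
    "timestamp", "chamber", "co2_ppm", "flow_lpm",
    "p_air_kpa", "p_cell_kpa", "t_air_c", "t_soil_c",
]
ENV_COLUMNS = ["timestamp", "chamber", "t_soil_c", "vwc", "t_air_amb_c", "rh"]
FLUX_COLUMNS = [
    "chamber", "treatment", "timestamp", "flux_umol_m2_s",
    "model", "r", "n_used", "usable", "flags",
]


@dataclass(frozen=True)
class Dialect:
    """File dialect: version tag, file->canonical column map, missing sentinel."""

    kind: str                      # 'raw' | 'env' | 'flux'
    columns: dict[str, str]        # file column name -> canonical name
    sentinel: str = "NA"
    version: int = 1

    @property
    def header_comment(self) -> str:
        return f"# chamberflux {self.kind} v{self.version}"


RAW_DIALECT = Dialect(kind="raw", columns={c: c for c in RAW_COLUMNS})
ENV_DIALECT = Dialect(kind="env", columns={c: c for c in ENV_COLUMNS})
FLUX_DIALECT = Dialect(kind="flux", columns={c: c for c in FLUX_COLUMNS})


def _write_csv(df: pd.DataFrame, path: str | Path, dialect: Dialect) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(dialect.header_comment + "\n")
        df.to_csv(fh, index=False, na_rep=dialect.sentinel, lineterminator="\n")


def _read_csv(path: str | Path, dialect: Dialect, parse_ts: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        comment="#",
        na_values=[dialect.sentinel],
        keep_default_na=True,
        float_precision="round_trip",  # lossless numeric round-trips
    )
    unknown = [c for c in df.columns if c not in dialect.columns]
    if unknown:
        raise ValueError(
            f"unknown columns {unknown} in {path}; dialect expects {sorted(dialect.columns)}"
        )
    df = df.rename(columns=dialect.columns)
    for col in parse_ts:
        if col in df:
            df[col] = pd.to_datetime(df[col], errors="coerce")
    return df


def write_raw(df: pd.DataFrame, path: str | Path, dialect: Dialect = RAW_DIALECT) -> None:
    """Write raw efflux records (one row per 10-s record)."""
    _write_csv(df[RAW_COLUMNS], path, dialect)


def read_raw(path: str | Path, dialect: Dialect = RAW_DIALECT) -> pd.DataFrame:
    """Read raw efflux records.

    Malformed rows (unparseable timestamp, missing/non-positive CO2) are
    flagged via a boolean ``valid`` column and counted in
    ``df.attrs['read_stats']`` — they are never silently dropped.  An
    empty file yields an empty frame with a warning.
    """
    df = _read_csv(path, dialect, parse_ts=["timestamp"])
    if df.empty:
        logger.warning("empty raw file: %s", path)
        df = pd.DataFrame(columns=RAW_COLUMNS)
    for col in RAW_COLUMNS:
        if col not in df:
            df[col] = np.nan
        if col not in ("timestamp",):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df[RAW_COLUMNS]
    valid = df["timestamp"].notna() & df["co2_ppm"].notna() & (df["co2_ppm"] > 0)
    df["valid"] = valid.to_numpy()
    stats = {"n_rows": len(df), "n_invalid": int((~valid).sum())}
    df.attrs["read_stats"] = stats
    if stats["n_invalid"]:
        logger.info("%s: %d of %d rows flagged invalid", path, stats["n_invalid"], stats["n_rows"])
    return df


def write_env(df: pd.DataFrame, path: str | Path, dialect: Dialect = ENV_DIALECT) -> None:
    """Write half-hourly environment records."""
    _write_csv(df[ENV_COLUMNS], path, dialect)


def read_env(path: str | Path, dialect: Dialect = ENV_DIALECT) -> pd.DataFrame:
    """Read half-hourly environment records (missing values left missing)."""
    df = _read_csv(path, dialect, parse_ts=["timestamp"])
    if df.empty:
        logger.warning("empty environment file: %s", path)
        return pd.DataFrame(columns=ENV_COLUMNS)
    for col in ENV_COLUMNS:
        if col != "timestamp":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[ENV_COLUMNS]


def flux_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    """Tidy one-row-per-closure table from flux records (stable column order)."""
    rows = [
        {
            "chamber": r.chamber,
            "treatment": r.treatment,
            "timestamp": r.start,
            "flux_umol_m2_s": r.flux,
            "model": r.model,
            "r": r.r,
            "n_used": r.n_used,
            "usable": r.usable,
            "flags": ";".join(r.flags),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=FLUX_COLUMNS)


def write_flux_table(
    records: Iterable[FluxRecord] | pd.DataFrame,
    path: str | Path,
    dialect: Dialect = FLUX_DIALECT,
) -> pd.DataFrame:
    """Write the processed flux table; returns the frame written.

    Empty input produces a header-only file; QC flags are serialized as
    semicolon-joined tokens.
    """
    df = records if isinstance(records, pd.DataFrame) else flux_frame(records)
    _write_csv(df[FLUX_COLUMNS], path, dialect)
    return df


def read_flux_table(path: str | Path, dialect: Dialect = FLUX_DIALECT) -> pd.DataFrame:
    df = _read_csv(path, dialect, parse_ts=["timestamp"])
    if df.empty:
        return pd.DataFrame(columns=FLUX_COLUMNS)
    df["flags"] = df["flags"].fillna("")
    df["usable"] = df["usable"].astype(bool)
    return df[FLUX_COLUMNS]


def segment_closures(
    df: pd.DataFrame,
    meta: dict[int, ChamberMeta],
    record_interval_s: float = 10.0,
    max_gap_factor: float = 1.5,
    min_records: int = 12,
    cycle_s: int = 3600,
) -> list[ClosureSegment]:
    """Split a time-sorted raw record stream into chamber closures.

    A new segment starts at every chamber-id change, at any time gap
    exceeding ``max_gap_factor`` record intervals (interrupted closures
    are *not* merged across a gap), and at each measurement-cycle
    boundary.  Segments shorter than ``min_records`` are flagged
    ``short_segment``.  Invalid records (``valid`` column False) are
    discarded before segmentation and counted; every valid record lands
    in exactly one segment.
    """
    if df.empty:
        return []
    if "valid" in df:
        n_discard = int((~df["valid"]).sum())
        if n_discard:
            logger.info("segmenting: discarding %d invalid records", n_discard)
        df = df[df["valid"]]
    if df.empty:
        return []
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError("records must be time-sorted before segmentation")

    missing = sorted(set(df["chamber"].astype(int)) - set(meta))
    if missing:
        raise ValueError(f"chamber ids absent from metadata: {missing}")

    ts = df["timestamp"]
    chamber = df["chamber"].astype(int)
    gap = ts.diff().dt.total_seconds() > max_gap_factor * record_interval_s
    cycle = ts.dt.floor(pd.Timedelta(seconds=cycle_s))
    new_seg = gap | (chamber != chamber.shift()) | (cycle != cycle.shift())
    new_seg.iloc[0] = True

    # slice contiguous runs on bare arrays: the stream can hold millions of
    # records, so per-group DataFrame construction is avoided
    starts = np.flatnonzero(new_seg.to_numpy())
    ends = np.append(starts[1:], len(df))
    ts_ns = ts.astype("int64").to_numpy()
    ch_np = chamber.to_numpy()
    cols = {
        c: df[c].to_numpy(dtype=float)
        for c in ("co2_ppm", "flow_lpm", "p_air_kpa", "t_air_c", "t_soil_c")
    }
    p_cell = df["p_cell_kpa"].to_numpy(dtype=float) if "p_cell_kpa" in df else None

    segments: list[ClosureSegment] = []
    for b, e in zip(starts, ends):
        ch = int(ch_np[b])
        seg = ClosureSegment(
            chamber=ch,
            start=pd.Timestamp(ts_ns[b]),
            offsets=(ts_ns[b:e] - ts_ns[b]) / 1e9,
            co2=cols["co2_ppm"][b:e],
            flow=cols["flow_lpm"][b:e],
            p_air=cols["p_air_kpa"][b:e],
            t_air=cols["t_air_c"][b:e],
            t_soil=cols["t_soil_c"][b:e],
            p_cell=None if p_cell is None else p_cell[b:e],
            treatment=meta[ch].treatment,
        )
        if seg.n < min_records:
            seg.flags.append("short_segment")
        segments.append(seg)
    return segments
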