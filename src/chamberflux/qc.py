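"""Quality control for chamber closures.

The screening procedure applied to every closure mirrors standard
practice for automated-chamber records: (1) the initial *dead band*
(records contaminated by lid-switching and tubing lag, typically 20–30 s
i.e. two to three 10-s records) is discarded; (2) ordinary least squares
of CO2 against closure time is fitted repeatedly — three fits in total by
default — removing records whose residual magnitude exceeds three
residual standard deviations at each pass; (3) the closure is usable only
if the final fit's Pearson correlation reaches a threshold (0.95 by
default) and enough records remain.

Closures with genuinely near-zero flux are a special case: the
correlation of a flat ramp is meaningless, so a closure whose fitted
slope's 95% confidence interval includes zero *and* whose residual
scatter is within the instrument-noise bound is marked ``usable_zero``
rather than rejected — winter fluxes are not discarded wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ClosureSegment, QCResult

__all__ = ["QCParams", "strip_dead_band", "reject_outliers", "usability", "run_qc"]


@dataclass(frozen=True)
class QCParams:
    """Tunable QC thresholds (defaults follow the procedure described above)."""

    dead_band: int = 3            # records stripped at closure start
    passes: int = 3               # total OLS fits (initial + repeats)
    outlier_m: float = 3.0        # rejection criterion, multiples of residual sd
    r_threshold: float = 0.95     # |Pearson r| usability threshold
    min_records: int = 10         # minimum retained records for a usable fit
    noise_bound_ppm: float = 1.0  # residual-sd bound for the usable-zero rule


def _ols(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float, float, float]:
    """Closed-form OLS of c on t: (slope, intercept, r, resid_sd, slope_se)."""
    n = len(t)
    tm, cm = t.mean(), c.mean()
    dt, dc = t - tm, c - cm
    stt = float(dt @ dt)
    if stt == 0.0:
        return math.nan, cm, math.nan, math.nan, math.nan
    stc = float(dt @ dc)
    scc = float(dc @ dc)
    slope = stc / stt
    intercept = cm - slope * tm
    resid = dc - slope * dt
    sse = float(resid @ resid)
    resid_sd = math.sqrt(sse / (n - 1)) if n > 1 else 0.0
    r = stc / math.sqrt(stt * scc) if scc > 0 else math.nan
    slope_se = math.sqrt(sse / ((n - 2) * stt)) if n > 2 else math.nan
    return slope, intercept, r, resid_sd, slope_se


def strip_dead_band(segment: ClosureSegment, k: int) -> tuple[ClosureSegment, np.ndarray]:
    """Drop the first ``k`` records; returns (trimmed segment, dropped indices).

    ``k = 0`` is the identity.  If ``k`` consumes the whole segment the
    returned (empty-trimmed) segment carries an ``unusable`` flag.
    """
    if k < 0:
        raise ValueError("dead-band length must be non-negative")
    k = min(k, segment.n)
    dropped = np.arange(k)
    if k == 0:
        return segment, dropped
    trimmed = segment.subset(np.arange(k, segment.n)) if k < segment.n else segment.subset(np.array([], dtype=int))
    if trimmed.n == 0:
        trimmed.flags.append("unusable")
    return trimmed, dropped


def reject_outliers(
    segment: ClosureSegment,
    passes: int = 3,
    m: float = 3.0,
    min_records: int = 10,
    _index_offset: int = 0,
) -> QCResult:
    """Iterative regression-based outlier rejection on one closure.

    Each pass fits OLS of CO2 against closure time on the currently
    retained records, computes the residual standard deviation, removes
    records with ``|residual| > m * sd`` and refits; iteration stops early
    when a pass removes nothing.  Zero residual scatter (an exact line)
    keeps everything — no division is performed.  If the retained count
    falls below ``min_records`` the closure is flagged unusable.
    """
    if passes < 1:
        raise ValueError("need at least one regression pass")
    if m <= 0:
        raise ValueError("outlier criterion m must be positive")
    n = segment.n
    rejected: dict[str, np.ndarray] = {}
    keep = np.arange(n)
    result = QCResult(n_records=n + _index_offset, retained=keep, rejected=rejected)
    if n < 3:
        result.flags.append("too_few_records")
        return result

    t = np.asarray(segment.offsets, dtype=float)
    c = np.asarray(segment.co2, dtype=float)
    slope = intercept = r = resid_sd = slope_se = math.nan
    for p in range(1, passes + 1):
        slope, intercept, r, resid_sd, slope_se = _ols(t[keep], c[keep])
        result.pass_sds.append(resid_sd)
        # residual scatter at floating rounding level is an exact line:
        # no real outliers exist and no rejection is performed
        if not math.isfinite(resid_sd) or resid_sd <= 1e-9:
            break
        resid = c[keep] - (intercept + slope * t[keep])
        bad = np.abs(resid) > m * resid_sd
        if not bad.any():
            break
        if p == passes:
            break  # criterion applied at each pass; no refit beyond the last
        rejected[f"outlier_pass{p}"] = keep[bad] + _index_offset
        keep = keep[~bad]
        if len(keep) < min_records:
            result.flags.append("too_few_records")
            break

    result.retained = keep + _index_offset
    result.slope, result.intercept = slope, intercept
    result.r, result.resid_sd, result.slope_se = r, resid_sd, slope_se
    if len(keep) < min_records:
        if "too_few_records" not in result.flags:
            result.flags.append("too_few_records")
    return result


def usability(qc: QCResult, params: QCParams = QCParams()) -> bool:
    """Usability predicate for a screened closure.

    Usable iff the final fit's ``|r|`` reaches the threshold and enough
    records remain; a near-zero-slope closure whose residual scatter is
    within the instrument-noise bound is marked ``usable_zero`` instead of
    being rejected.  Sets ``qc.usable`` and appends explanatory flags.
    """
    if qc.n_used < params.min_records or "too_few_records" in qc.flags:
        qc.usable = False
        if "too_few_records" not in qc.flags:
            qc.flags.append("too_few_records")
        return False
    if math.isfinite(qc.r) and abs(qc.r) >= params.r_threshold:
        qc.usable = True
        return True
    # near-zero flux: r is meaningless when the true slope ~ 0
    if (
        math.isfinite(qc.slope_se)
        and math.isfinite(qc.resid_sd)
        and qc.resid_sd <= params.noise_bound_ppm
    ):
        tcrit = stats.t.ppf(0.975, qc.n_used - 2)
        if abs(qc.slope) <= tcrit * qc.slope_se:
            qc.usable = True
            qc.flags.append("usable_zero")
            return True
    qc.usable = False
    qc.flags.append("low_r")
    return False


def run_qc(segment: ClosureSegment, params: QCParams = QCParams()) -> QCResult:
    """Full screening of one closure: dead band, outlier rejection, usability.

    Indices in the result refer to the *original* record positions of the
    segment; retained and rejected indices always partition them.
    """
    n = segment.n
    if n - params.dead_band < max(params.min_records, 3):
        qc = QCResult(
            n_records=n,
            retained=np.array([], dtype=int),
            rejected={"short_segment": np.arange(n)},
        )
        qc.flags.append("short_segment")
        qc.usable = False
        return qc

    trimmed, dead = strip_dead_band(segment, params.dead_band)
    qc = reject_outliers(
        trimmed,
        passes=params.passes,
        m=params.outlier_m,
        min_records=params.min_records,
        _index_offset=params.dead_band,
    )
    if len(dead):
        qc.rejected["dead_band"] = dead
    if "short_segment" in segment.flags:
        qc.flags.append("short_segment")
        qc.usable = False
        qc.flags.append("unusable_short")
        return qc
    usability(qc, params)
    return qc
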