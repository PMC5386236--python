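"""Core data structures shared across the chamberflux pipeline.

The atomic unit of measurement is one chamber *closure*: an automated
chamber lid closes for a few minutes while air is circulated through an
infrared gas analyser (IRGA), and the soil CO2 efflux is inferred from
the rate of CO2 accumulation in the chamber headspace.  Everything
downstream (quality control, flux computation, treatment-level analysis)
operates on :class:`ClosureSegment` objects and the records derived from
them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Ideal gas constant, Pa m3 K-1 mol-1.
R_GAS = 8.314

#: Offset between Celsius and Kelvin.
CELSIUS_TO_K = 273.15

#: Carbon molar mass, g mol-1 (for aggregation to carbon sums).
CARBON_G_PER_MOL = 12.011

#: Recognised treatment labels: control plots measure total soil efflux
#: (Rs), trenched plots exclude roots and measure heterotrophic
#: respiration (Rh), warmed-trenched plots measure Rh under experimental
#: soil warming (Rhw).
TREATMENTS = ("control", "trenched", "warmed_trenched")


def flux_coefficient(vs_ratio: float) -> float:
    """Chamber coefficient ``1000 * (V/S) / R`` for kPa-based flux equations.

    With the effective volume-to-surface ratio V/S = 0.5 m this evaluates
    to 60.14 (4 s.f.), the constant appearing in the simplified
    closed-chamber flux equation.  The exact value is used everywhere so
    that forward and inverse computations are mutually consistent.

    Parameters
    ----------
    vs_ratio
        Effective chamber volume over enclosed soil surface area, m.
    """
    if vs_ratio <= 0:
        raise ValueError(f"V/S ratio must be positive, got {vs_ratio}")
    return 1000.0 * vs_ratio / R_GAS


@dataclass(frozen=True)
class ChamberMeta:
    """Static description of one chamber: identity, treatment, geometry."""

    chamber: int
    treatment: str
    vs_ratio: float = 0.5  # effective V/S, m

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.vs_ratio <= 0:
            raise ValueError("V/S ratio must be positive")


def default_chamber_meta(
    n_chambers: int = 15, vs_ratio: float = 0.5
) -> dict[int, ChamberMeta]:
    """Chamber -> metadata map with chambers split into three equal treatment
    groups in id order (low ids control, middle trenched, high warmed-trenched),
    mirroring a 15-chamber site with five chambers per treatment."""
    per_group = max(1, n_chambers // 3)
    meta = {}
    for ch in range(1, n_chambers + 1):
        group = min((ch - 1) // per_group, 2)
        meta[ch] = ChamberMeta(chamber=ch, treatment=TREATMENTS[group], vs_ratio=vs_ratio)
    return meta


@dataclass
class ClosureSegment:
    """Records from a single chamber closure.

    Offsets are seconds since the closure start; all per-record arrays
    share one length.  ``w`` (water-vapour mole fraction, mmol mol-1) is
    optional because the deployed IRGA cannot measure water vapour — it
    only exists for synthetic closures exercising the full flux equation.
    """

    chamber: int
    start: pd.Timestamp
    offsets: np.ndarray          # s since closure start
    co2: np.ndarray              # μmol mol-1 (ppm)
    flow: np.ndarray             # l min-1
    p_air: np.ndarray            # kPa, chamber-height ambient pressure
    t_air: np.ndarray            # °C, chamber air temperature
    t_soil: np.ndarray           # °C, 5-cm soil temperature
    p_cell: Optional[np.ndarray] = None   # kPa, IRGA cell pressure
    w: Optional[np.ndarray] = None        # mmol H2O mol-1
    treatment: Optional[str] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arrays = [self.offsets, self.co2, self.flow, self.p_air, self.t_air, self.t_soil]
        arrays += [a for a in (self.p_cell, self.w) if a is not None]
        n = len(self.offsets)
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-record arrays must share one length")
        if n > 1 and np.any(np.diff(np.asarray(self.offsets, dtype=float)) <= 0):
            raise ValueError("record offsets must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.offsets)

    def subset(self, idx: np.ndarray) -> "ClosureSegment":
        """New segment containing only the records at ``idx`` (original offsets kept)."""
        take = lambda a: None if a is None else np.asarray(a)[idx]
        return dataclasses.replace(
            self,
            offsets=take(self.offsets),
            co2=take(self.co2),
            flow=take(self.flow),
            p_air=take(self.p_air),
            t_air=take(self.t_air),
            t_soil=take(self.t_soil),
            p_cell=take(self.p_cell),
            w=take(self.w),
            flags=list(self.flags),
        )


@dataclass
class QCResult:
    """Outcome of the dead-band / iterative-outlier-rejection procedure.

    ``retained`` and the index arrays in ``rejected`` partition the
    original record indices of the segment that was screened.  The final
    ordinary-least-squares fit of CO2 against closure time is stored so
    the flux step can reuse it without refitting.
    """

    n_records: int
    retained: np.ndarray
    rejected: dict[str, np.ndarray]
    slope: float = np.nan        # ppm s-1
    intercept: float = np.nan    # ppm
    r: float = np.nan            # Pearson correlation of the final fit
    resid_sd: float = np.nan     # ppm
    slope_se: float = np.nan     # ppm s-1
    pass_sds: list[float] = field(default_factory=list)
    usable: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_used(self) -> int:
        return len(self.retained)

    def check_partition(self) -> bool:
        """True when retained + rejected indices exactly cover the segment."""
        parts = [self.retained] + list(self.rejected.values())
        allidx = np.concatenate([np.asarray(p, dtype=int) for p in parts]) if parts else np.array([], int)
        return len(allidx) == self.n_records and len(np.unique(allidx)) == self.n_records


@dataclass
class FluxRecord:
    """One QC'd efflux estimate for one chamber closure."""

    chamber: int
    start: pd.Timestamp
    flux: float                  # μmol CO2 m-2 s-1
    model: str                   # 'linear' | 'average' | 'full'
    p_air_kpa: float
    t_air_c: float
    t_air_source: str            # 'chamber' | 'site'
    r: float
    n_used: int
    usable: bool
    treatment: Optional[str] = None
    flags: list[str] = field(default_factory=list)


@dataclass
class CalibrationSet:
    """Pre-treatment calibration coefficients Qc per treatment.

    Qc(treatment) is the ratio of the mean hourly flux over *all* trenched
    chambers to the mean hourly flux of that treatment's chambers over a
    window preceding the warming onset; multiplying the treatment series
    by its Qc removes the initial spatial heterogeneity between groups.
    """

    qc: dict[str, float]
    window: tuple[pd.Timestamp, pd.Timestamp]
    n_hours: dict[str, int] = field(default_factory=dict)


@dataclass
class WarmingEffect:
    """Warming effect Fe on heterotrophic respiration, % per °C."""

    fe_pct_per_c: float
    delta_t_c: float
    calibrated_mean: dict[str, float]   # Qc-calibrated period-mean fluxes
    period: tuple[pd.Timestamp, pd.Timestamp]
    n_hours: int
    mode: str = "period_mean"           # or 'hourly'


@dataclass
class Q10Fit:
    """Exponential temperature-sensitivity fit R = R_ref * Q10^((T - T_ref)/10)."""

    q10: float
    flux_ref: float              # μmol m-2 s-1 at t_ref
    t_ref: float                 # °C
    slope: float                 # b in ln R = a + b T
    intercept: float             # a
    slope_se: float
    r2: float
    n: int
    n_excluded: int              # non-positive fluxes dropped from the log fit
    window: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None
    method: str = "ols"

    def predict(self, t_soil: np.ndarray | float) -> np.ndarray | float:
        """Predicted flux at soil temperature ``t_soil`` (°C)."""
        return self.flux_ref * self.q10 ** ((np.asarray(t_soil, dtype=float) - self.t_ref) / 10.0)


@dataclass
class FaultSpec:
    """Instrument fault to inject into synthetic raw records.

    kinds: ``pump_stop`` (air flow through the IRGA stops; concentration
    plateaus then decays and the flow column drops to ~0), ``leak``
    (chamber lid leaks; the concentration ramp saturates concavely),
    ``fan`` (mixing fan stops; record-to-record scatter inflates).
    """

    kind: str
    chamber: int
    start: pd.Timestamp
    end: pd.Timestamp
    leak_attenuation: float = 0.5      # 0 = no leak .. 1 = fully saturating
    fan_noise_factor: float = 8.0      # scatter inflation under fan failure
    pump_decay_ppm: float = 30.0       # decay amplitude toward ambient
    pump_decay_tau_s: float = 150.0    # decay time scale of the stagnating cell
    pump_plateau_frac: float = 0.55    # fraction of closure at the plateau

    KINDS = ("pump_stop", "leak", "fan")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fault kind {self.kind!r}; expected one of {self.KINDS}")


@dataclass
class TruthBundle:
    """Synthetic ground truth emitted alongside generated raw files.

    ``flux`` has one row per generated closure with the noise-free efflux
    the generator used, plus the recorded and unwarmed soil temperatures.
    """

    flux: pd.DataFrame                   # chamber, timestamp, true_flux, t_soil, t_soil_unwarmed, treatment
    q10: float
    fe_pct_per_c: float
    warming_offset_c: float
    chamber_offsets: dict[int, float]
    warming_start: Optional[pd.Timestamp]
    faults: list[FaultSpec] = field(default_factory=list)
    spikes: pd.DataFrame = field(default_factory=pd.DataFrame)  # chamber, timestamp, magnitude_ppm
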