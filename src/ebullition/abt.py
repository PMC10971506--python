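"""Automated bubble trap (ABT) log processing: from raw 30-s fill-height
records to ebullition flux series.

An ABT funnels rising bubbles (funnel opening 0.78 m2) into a calibrated
tube and logs gas fill height, gas temperature and pressure every 30 s.  The
tube is flushed by a valve when full, or every 12 hours.  Processing steps:

1. :func:`segment_flushes` — split the log into accumulation segments at
   flush events, turning fill-height differences into per-step gas volumes.
2. :func:`standardize_volume` — refer collected volumes to standard pressure
   (1 atm) and temperature (20 degC) via the ideal gas law.
3. :func:`methane_mass` — convert a gas volume to methane mass using a
   constant 68.9 % methane fraction in the bubbles.
4. :func:`flux_series` — sum volumes/masses over fixed intervals and divide
   by funnel area and interval length, masking intervals without coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import RegularSeries, as_interval

R_GAS = 8.314462618      # J mol-1 K-1
M_CH4 = 16.04            # g mol-1
STANDARD_PRESSURE = 101325.0   # Pa (1 atm)
STANDARD_TEMPERATURE = 293.15  # K (20 degC)

SUPPORTED_INTERVALS = ("5min", "10min", "1h", "1d")


@dataclass
class CalibrationSpec:
    """Trap geometry and gas constants used in flux computation."""

    tube_cross_section: float = 1.0e-3   # m2, fill height -> volume
    funnel_area: float = 0.78            # m2
    methane_fraction: float = 0.689      # volumetric CH4 fraction in bubbles
    standard_pressure: float = STANDARD_PRESSURE    # Pa
    standard_temperature: float = STANDARD_TEMPERATURE  # K
    gas_constant: float = R_GAS
    molar_mass_ch4: float = M_CH4
    max_fill_height: float = 0.5         # m, valve trigger
    flush_period: pd.Timedelta = pd.Timedelta(hours=12)
    jitter_tolerance: float = 1.0e-3     # m; smaller drops are sensor noise
    coverage_fraction: float = 0.8       # valid-interval rule

    def __post_init__(self):
        for name in ("tube_cross_section", "funnel_area", "standard_pressure",
                     "standard_temperature", "gas_constant", "molar_mass_ch4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.methane_fraction <= 1:
            raise ValueError("methane_fraction must be in (0, 1]")


@dataclass
class RawABTLog:
    """30-s trap records: fill height (m), gas temperature (degC in files,
    kelvin in computation), pressure (kPa in files, Pa in computation)."""

    timestamps: pd.DatetimeIndex
    fill_height: np.ndarray      # m
    temperature_c: np.ndarray    # degC
    pressure_kpa: np.ndarray     # kPa
    flush_flag: np.ndarray       # bool, True on flush (reset) records
    site: str = "site"

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("ABT log timestamps must be strictly increasing")
        self.fill_height = np.asarray(self.fill_height, dtype=float)
        if (self.fill_height < 0).any():
            raise ValueError("fill height cannot be negative")
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.pressure_kpa = np.asarray(self.pressure_kpa, dtype=float)
        self.flush_flag = np.asarray(self.flush_flag, dtype=bool)

    def __len__(self):
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fill_height_m": self.fill_height,
            "temp_C": self.temperature_c,
            "pressure_kPa": self.pressure_kpa,
            "flush_flag": self.flush_flag.astype(int),
        }, index=pd.Index(self.timestamps, name="timestamp"))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, site: str = "site") -> "RawABTLog":
        return cls(
            timestamps=pd.DatetimeIndex(frame.index),
            fill_height=frame["fill_height_m"].to_numpy(),
            temperature_c=frame["temp_C"].to_numpy(),
            pressure_kpa=frame["pressure_kPa"].to_numpy(),
            flush_flag=frame["flush_flag"].to_numpy().astype(bool),
            site=site,
        )


@dataclass
class Segment:
    """One accumulation run between flushes."""

    timestamps: pd.DatetimeIndex   # per-increment stamps (end of 30-s step)
    volumes_m3: np.ndarray         # per-step collected gas volume at in-situ T, P
    temperature_k: np.ndarray
    pressure_pa: np.ndarray
    fault_mask: np.ndarray         # True where the record is a flagged fault


@dataclass
class FluxSeries:
    """Site-labelled gas and methane flux on a fixed grid."""

    site: str
    gas_flux: RegularSeries        # mL m-2 d-1 (volume at STP)
    methane_flux: RegularSeries    # mg CH4 m-2 d-1
    meta: dict = field(default_factory=dict)


def standardize_volume(volume, temperature_k, pressure_pa, cal: CalibrationSpec | None = None):
    """Refer a gas volume at in-situ (T, P) to standard pressure/temperature.

    V_std = V * (P / P_std) * (T_std / T); monotone increasing in P and
    decreasing in T.
    """
    cal = cal or CalibrationSpec()
    t = np.asarray(temperature_k, dtype=float)
    p = np.asarray(pressure_pa, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("temperature and pressure must be strictly positive")
    out = np.asarray(volume, dtype=float) * (p / cal.standard_pressure) * (
        cal.standard_temperature / t)
    return out if np.ndim(out) else float(out)


def methane_mass(volume_m3, temperature_k, pressure_pa, cal: CalibrationSpec | None = None):
    """Methane mass (mg) in a gas volume at in-situ (T, P).

    n = P V / (R T); mass = n * f_CH4 * M_CH4 (M in g/mol, result in mg).
    """
    cal = cal or CalibrationSpec()
    t = np.asarray(temperature_k, dtype=float)
    p = np.asarray(pressure_pa, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise ValueError("temperature and pressure must be strictly positive")
    mol = p * np.asarray(volume_m3, dtype=float) / (cal.gas_constant * t)
    out = mol * cal.methane_fraction * cal.molar_mass_ch4 * 1e3  # g -> mg
    return out if np.ndim(out) else float(out)


def segment_flushes(log: RawABTLog, cal: CalibrationSpec | None = None) -> list[Segment]:
    """Split an ABT log into accumulation segments of per-step volumes.

    Within a segment the collected volume per 30-s step is
    ``tube_cross_section * max(dh, 0)``; negative height steps within the
    jitter tolerance are clipped to zero, larger unflagged drops are treated
    as a reset boundary and the offending record is flagged as a fault so the
    enclosing interval can be masked rather than silently zeroed.
    """
    cal = cal or CalibrationSpec()
    n = len(log)
    if n < 2:
        return []
    dh = np.diff(log.fill_height)
    is_flush = log.flush_flag[1:]
    fault = np.zeros(n - 1, dtype=bool)
    big_drop = (dh < -cal.jitter_tolerance) & ~is_flush
    fault |= big_drop
    boundary = is_flush | big_drop

    steps = np.clip(dh, 0.0, None)
    steps[boundary] = 0.0
    vols = steps * cal.tube_cross_section

    segments: list[Segment] = []
    idx = np.flatnonzero(boundary)
    starts = np.concatenate([[0], idx + 1])
    ends = np.concatenate([idx + 1, [n - 1]])
    for s, e in zip(starts, ends):
        if e <= s:
            continue
        segments.append(Segment(
            timestamps=log.timestamps[s + 1: e + 1],
            volumes_m3=vols[s:e],
            temperature_k=log.temperature_c[s + 1: e + 1] + 273.15,
            pressure_pa=log.pressure_kpa[s + 1: e + 1] * 1e3,
            fault_mask=fault[s:e],
        ))
    return segments


def flux_series(
    segments: list[Segment],
    cal: CalibrationSpec,
    interval: str | pd.Timedelta,
    site: str = "site",
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> FluxSeries:
    """Per-interval gas (STP) and methane flux from accumulation segments.

    flux = sum(standardized volumes) / funnel_area / (interval in days).
    Intervals whose 30-s record coverage is below ``cal.coverage_fraction``
    (or that contain flagged faults) are masked, never zero-filled.
    """
    key = str(interval).lower().replace(" ", "")
    if key not in SUPPORTED_INTERVALS and not isinstance(interval, pd.Timedelta):
        raise ValueError(
            f"unsupported interval {interval!r}; choose one of {SUPPORTED_INTERVALS}")
    step = as_interval(interval)

    if not segments:
        raise ValueError("flux_series: no segments (empty log)")
    stamps = pd.DatetimeIndex(np.concatenate([s.timestamps.asi8 for s in segments]))
    v_std = np.concatenate([
        standardize_volume(s.volumes_m3, s.temperature_k, s.pressure_pa, cal)
        for s in segments])
    mass = np.concatenate([
        methane_mass(s.volumes_m3, s.temperature_k, s.pressure_pa, cal)
        for s in segments])
    faults = np.concatenate([s.fault_mask for s in segments])

    t0 = span[0] if span else stamps[0].floor(step)
    t1 = span[1] if span else stamps[-1].ceil(step)
    grid = pd.date_range(t0 + step, t1, freq=step)
    if len(grid) == 0:
        raise ValueError("flux_series: log shorter than one interval")

    bin_idx = np.searchsorted(grid.asi8, stamps.asi8, side="left")
    ok = (bin_idx >= 0) & (bin_idx < len(grid))
    nbins = len(grid)
    vol_sum = np.bincount(bin_idx[ok], weights=v_std[ok], minlength=nbins)
    mass_sum = np.bincount(bin_idx[ok], weights=mass[ok], minlength=nbins)
    rec_count = np.bincount(bin_idx[ok], minlength=nbins)
    fault_count = np.bincount(bin_idx[ok], weights=faults[ok].astype(float), minlength=nbins)

    slots = step / pd.Timedelta(seconds=30)
    covered = rec_count >= cal.coverage_fraction * slots
    good = covered & (fault_count == 0)

    days = step / pd.Timedelta(days=1)
    gas = np.where(good, vol_sum * 1e6 / cal.funnel_area / days, np.nan)   # m3 -> mL
    ch4 = np.where(good, mass_sum / cal.funnel_area / days, np.nan)

    mk = lambda vals, units, name: RegularSeries(
        start=grid[0], interval=step, values=vals, units=units, name=name)
    return FluxSeries(
        site=site,
        gas_flux=mk(gas, "mL m-2 d-1", f"{site}_gas_flux"),
        methane_flux=mk(ch4, "mg CH4 m-2 d-1", f"{site}_ch4_flux"),
        meta={"n_segments": len(segments), "n_faults": int(faults.sum())},
    )


def process_log(
    log: RawABTLog,
    cal: CalibrationSpec | None = None,
    interval: str | pd.Timedelta = "1d",
) -> FluxSeries:
    """Convenience wrapper: segment a log and compute a flux series."""
    cal = cal or CalibrationSpec()
    return flux_series(segment_flushes(log, cal), cal, interval, site=log.site)
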