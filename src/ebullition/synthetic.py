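"""Synthetic drivers and multi-site episodic ebullition with known ground
truth.

The generator emulates the statistical structure of a multi-year bubble-trap
monitoring campaign in a subtropical polymictic reservoir:

* a seasonal bottom-temperature cycle confined to 16-23.2 degC;
* band-limited synoptic atmospheric-pressure variability (periods of a few
  days), the main large-scale ebullition trigger;
* bottom dissolved oxygen anti-correlated with thermal stratification;
* zero-inflated, episodic ebullition produced by a latent sediment gas store:
  methane production follows a Q10-style temperature law, gas accumulates,
  and a stochastic fraction is vented when the hydrostatic+atmospheric
  pressure falls quickly, when near-bed currents exceed a threshold, or when
  the store overflows.

A single coupling parameter ``synchrony_kappa`` in [0, 1] interpolates every
site-level trigger between a shared realization (kappa = 1: sites fire in
lockstep) and independent site-specific realizations (kappa = 0).  Shared
and site random draws are combined through a Gaussian copula so marginal
distributions do not change with kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abt import CalibrationSpec, FluxSeries, RawABTLog, STANDARD_PRESSURE, STANDARD_TEMPERATURE
from .timeseries import RegularSeries, as_interval

GRAVITY = 9.81          # m s-2
WATER_DENSITY = 998.0   # kg m-3, for hydrostatic pressure
SECONDS_PER_DAY = 86400.0


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults emulate the monitored system."""

    seed: int = 0
    n_sites: int = 3
    start: str | pd.Timestamp = "2018-07-01"
    end: str | pd.Timestamp = "2019-07-01"
    base_interval: str = "10min"

    # drivers
    temp_mean: float = 19.6            # degC, bottom water annual mean
    temp_seasonal_amp: float = 3.6     # degC -> seasonal range 16.0-23.2
    strat_delta_max: float = 4.0       # degC, peak surface-bottom difference
    pressure_mean: float = 92.0        # kPa (site altitude ~900 m)
    pressure_synoptic_amp: float = 0.8  # kPa std of the synoptic band
    synoptic_band_days: tuple[float, float] = (2.5, 8.5)
    water_depth_mean: float = 11.5     # m at the trap site
    trap_depth: float = 2.0            # m below surface (trap submergence)
    wind_mean: float = 2.5             # m s-1
    current_mean: float = 0.025        # m s-1 near-bed
    do_surface_mean: float = 8.5       # mg L-1
    do_bottom_max: float = 8.0         # mg L-1 under mixed conditions
    chla_mean: float = 6.0             # ug L-1 daily

    # sediment store and triggers
    production_rate_at_20C: float = 40.0   # mg CH4 m-2 d-1
    q10_like_factor: float = 4.0
    storage_capacity: float = 4600.0       # mg CH4 m-2
    initial_storage_fraction: float = 0.5
    pressure_trigger: float = 0.5          # kPa per day drop rate
    current_trigger: float = 0.05          # m s-1
    release_fraction_mean: float = 0.06
    release_fraction_sd: float = 0.02
    synchrony_kappa: float = 0.8           # [0, 1]
    zero_inflation_target: float = 0.5     # target P(zero daily flux | triggered day)

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if as_interval(self.base_interval) <= pd.Timedelta(0):
            raise ValueError("base_interval must be positive")
        if not 0.0 <= self.synchrony_kappa <= 1.0:
            raise ValueError("synchrony_kappa must be in [0, 1]")
        if self.storage_capacity <= 0:
            raise ValueError("storage_capacity must be positive")
        if not 0.0 < self.release_fraction_mean <= 1.0:
            raise ValueError("release_fraction_mean must be in (0, 1]")
        if not 0.0 <= self.zero_inflation_target < 1.0:
            raise ValueError("zero_inflation_target must be in [0, 1)")

    @property
    def grid(self) -> pd.DatetimeIndex:
        step = as_interval(self.base_interval)
        return pd.date_range(self.start + step, self.end, freq=step)


@dataclass
class DriverBundle:
    """One RegularSeries per environmental driver, on the configured grid
    (chlorophyll-a on its own daily grid, never downscaled)."""

    temp_bottom: RegularSeries     # degC
    temp_surface: RegularSeries    # degC
    do_bottom: RegularSeries       # mg L-1
    do_surface: RegularSeries      # mg L-1
    atm_pressure: RegularSeries    # kPa
    water_depth: RegularSeries     # m
    wind_speed: RegularSeries      # m s-1
    current_speed: RegularSeries   # m s-1
    w_rms: RegularSeries           # m s-1, vertical-velocity fluctuation
    dissipation: RegularSeries     # W kg-1
    chla_daily: RegularSeries      # ug L-1, daily grid
    meta: dict = field(default_factory=dict)

    def on_grid(self) -> list[RegularSeries]:
        """All base-grid series (excludes the daily-only chlorophyll)."""
        return [self.temp_bottom, self.temp_surface, self.do_bottom,
                self.do_surface, self.atm_pressure, self.water_depth,
                self.wind_speed, self.current_speed, self.w_rms,
                self.dissipation]

    def total_pressure_kpa(self) -> RegularSeries:
        """Atmospheric + hydrostatic pressure at the sediment (kPa)."""
        hydro = WATER_DENSITY * GRAVITY * self.water_depth.values / 1e3
        return self.atm_pressure.copy(
            values=self.atm_pressure.values + hydro,
            units="kPa", name="total_pressure")


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sigma``."""
    eps = rng.standard_normal(n) * sigma * np.sqrt(1.0 - phi**2)
    out = np.empty(n)
    out[0] = rng.standard_normal() * sigma
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return out


def _band_limited(rng: np.random.Generator, n: int, dt_days: float,
                  band_days: tuple[float, float], sigma: float) -> np.ndarray:
    """Gaussian noise with power confined to periods in ``band_days``."""
    freqs = np.fft.rfftfreq(n, d=dt_days)  # cycles per day
    lo, hi = 1.0 / band_days[1], 1.0 / band_days[0]
    keep = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(keep.sum())
    if k == 0:
        raise ValueError("series too short for the requested synoptic band")
    spec[keep] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def gen_drivers(config: SyntheticConfig) -> DriverBundle:
    """Deterministic-for-seed bundle of correlated environmental drivers."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n = len(grid)
    step = as_interval(config.base_interval)
    dt_days = step / pd.Timedelta(days=1)

    # seasonal phase: peak warmth around Feb 1 (southern-hemisphere summer)
    doy = grid.dayofyear.to_numpy() + grid.hour.to_numpy() / 24.0
    season = np.cos(2.0 * np.pi * (doy - 32.0) / 365.25)
    hour = grid.hour.to_numpy() + grid.minute.to_numpy() / 60.0
    diurnal = np.sin(2.0 * np.pi * hour / 24.0)

    temp_bottom = config.temp_mean + config.temp_seasonal_amp * season

    # stratification: surface warms above the bottom in summer, modulated by
    # a diurnal cycle and synoptic weather; never cooler than the bottom
    strat_noise = _ar1(rng, n, phi=0.999 if dt_days < 0.05 else 0.97, sigma=0.8)
    delta_t = np.clip(
        0.5 * config.strat_delta_max * (season + 1.0)
        + 0.3 * diurnal + strat_noise, 0.0, None)
    temp_surface = temp_bottom + delta_t

    # bottom DO: high under mixed conditions, anoxic under stratification
    do_noise = _ar1(rng, n, phi=0.995, sigma=0.4)
    do_bottom = np.clip(config.do_bottom_max - 2.2 * delta_t + do_noise, 0.0, None)
    do_surface = np.clip(config.do_surface_mean + 0.3 * season
                         + _ar1(rng, n, 0.99, 0.3), 0.0, None)

    atm = (config.pressure_mean + 0.3 * season
           + _band_limited(rng, n, dt_days, config.synoptic_band_days,
                           config.pressure_synoptic_amp))

    depth = (config.water_depth_mean - 0.4 * _ar1(rng, n, 0.9995, 0.5)
             .clip(-1.0, 1.0))

    wind = np.clip(config.wind_mean * (1.0 + 0.35 * diurnal)
                   + _ar1(rng, n, 0.97, 1.2), 0.05, None)

    # episodic near-bed currents: lognormal modulation of a slow AR(1)
    current = config.current_mean * np.exp(_ar1(rng, n, 0.98, 0.7) - 0.245)
    w_rms = 0.003 + 0.25 * current * np.abs(1.0 + _ar1(rng, n, 0.9, 0.3))
    dissipation = 1e-8 * np.exp(-0.4 * delta_t + _ar1(rng, n, 0.95, 0.9))

    mk = lambda v, units, name: RegularSeries(
        start=grid[0], interval=step, values=v, units=units, name=name)

    # daily chlorophyll: higher after mixing (winter), on its own daily grid
    daily_grid = pd.date_range(grid[0].ceil("1d"), grid[-1], freq="1d")
    doy_d = daily_grid.dayofyear.to_numpy()
    season_d = np.cos(2.0 * np.pi * (doy_d - 32.0) / 365.25)
    chla = np.clip(config.chla_mean - 2.0 * season_d
                   + _ar1(rng, len(daily_grid), 0.9, 1.0), 0.2, None)

    return DriverBundle(
        temp_bottom=mk(temp_bottom, "degC", "temp_bottom"),
        temp_surface=mk(temp_surface, "degC", "temp_surface"),
        do_bottom=mk(do_bottom, "mg L-1", "do_bottom"),
        do_surface=mk(do_surface, "mg L-1", "do_surface"),
        atm_pressure=mk(atm, "kPa", "atm_pressure"),
        water_depth=mk(depth, "m", "water_depth"),
        wind_speed=mk(wind, "m s-1", "wind_speed"),
        current_speed=mk(current, "m s-1", "current_speed"),
        w_rms=mk(w_rms, "m s-1", "w_rms"),
        dissipation=mk(dissipation, "W kg-1", "dissipation"),
        chla_daily=RegularSeries(start=daily_grid[0], interval=pd.Timedelta(days=1),
                                 values=chla, units="ug L-1", name="chla"),
        meta={"seed": config.seed},
    )


def pressure_drop_rate(total_pressure: RegularSeries,
                       window: pd.Timedelta = pd.Timedelta(hours=6)) -> np.ndarray:
    """Backward pressure drop rate (kPa per day) over a 6-h window.

    Positive values mean falling pressure.  The first window is padded with
    zeros (no drop information yet).
    """
    k = max(1, int(round(window / total_pressure.interval)))
    p = total_pressure.values
    drop = np.zeros_like(p)
    wdays = (k * total_pressure.interval) / pd.Timedelta(days=1)
    drop[k:] = (p[:-k] - p[k:]) / wdays
    return drop


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd**2
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ValueError("release fraction sd too large for the given mean")
    nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _copula_uniform(shared_z: np.ndarray, site_z: np.ndarray, kappa: float) -> np.ndarray:
    """Uniform marginals with inter-site dependence controlled by kappa."""
    z = kappa * shared_z + np.sqrt(1.0 - kappa**2) * site_z
    scale = np.sqrt(kappa**2 + (1.0 - kappa**2))  # = 1; kept for clarity
    return stats.norm.cdf(z / scale)


def _calibrate_trigger_scale(drop, current, day_idx, p_thr, c_thr, target,
                             tol=0.005, max_iter=60):
    """Common multiplier on both trigger thresholds such that the fraction
    of days without any triggered step matches ``target``.

    The configured thresholds fix the relative weight of the pressure-drop
    and current pathways; the multiplier sets the overall exceedance level.
    """
    n_days = day_idx.max() + 1

    def zero_fraction(m):
        trig = (drop > m * p_thr) | (current > m * c_thr)
        hit = np.zeros(n_days, dtype=bool)
        hit[day_idx[trig]] = True
        return 1.0 - hit.mean()

    lo, hi = 1.0 / 16.0, 16.0
    if zero_fraction(lo) > target:
        return lo
    if zero_fraction(hi) < target:
        return hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        if zero_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + tol:
            break
    return np.sqrt(lo * hi)


def gen_ebullition(drivers: DriverBundle, config: SyntheticConfig) -> list[FluxSeries]:
    """Latent-store ebullition for each site.

    Per site and time step (length ``delta`` days) the sediment store obeys

        S <- S + production(T) * delta - R
        production(T) = production_rate_at_20C * q10_like_factor**((T-20)/10)

    Release happens only while a trigger is active — the pressure drop rate
    exceeds ``pressure_trigger``, the near-bed current exceeds
    ``current_trigger`` (both scaled by a common calibration factor so the
    fraction of release-free days matches ``zero_inflation_target``), or the
    store overflows ``storage_capacity``.  On each day with triggered steps
    a Beta-distributed fraction of the store is vented; that day total is
    allocated stochastically across the day's triggered steps (weights
    proportional to trigger excess times exponential draws), so the fine-
    scale timing of release is far noisier than its daily aggregate.
    ``synchrony_kappa`` mixes every random ingredient between a shared and a
    site-specific realization.  Fluxes are non-negative and zero-inflated.
    """
    if not 0.0 <= config.synchrony_kappa <= 1.0:
        raise ValueError("synchrony_kappa must be in [0, 1]")
    kappa = config.synchrony_kappa
    grid = drivers.temp_bottom.index
    n = len(grid)
    step = drivers.temp_bottom.interval
    delta = step / pd.Timedelta(days=1)
    day_ns = 86_400_000_000_000
    day_idx = ((grid.asi8 - 1) // day_ns).astype(np.int64)
    day_idx -= day_idx[0]
    n_days = int(day_idx.max()) + 1

    total_p = drivers.total_pressure_kpa()
    shared_drop = pressure_drop_rate(total_p)
    shared_current = drivers.current_speed.values
    temp = drivers.temp_bottom.values
    production = (config.production_rate_at_20C
                  * config.q10_like_factor ** ((temp - 20.0) / 10.0))

    # reproducible independent streams: one shared, one per site
    root = np.random.default_rng(config.seed).spawn(config.n_sites + 1)
    shared_rng, site_rngs = root[0], root[1:]
    shared_z_frac = shared_rng.standard_normal(n_days)
    shared_z_alloc = shared_rng.standard_normal(n)
    drop_sd = shared_drop.std() or 1.0
    cur_log = np.log(np.clip(shared_current, 1e-9, None))
    cur_sd = cur_log.std() or 1.0

    a, b = _beta_params(config.release_fraction_mean, config.release_fraction_sd)

    out: list[FluxSeries] = []
    for j, rng in enumerate(site_rngs):
        # site-specific AR(1) perturbations of the shared triggers
        drop_j = kappa * shared_drop + (1.0 - kappa) * _ar1(rng, n, 0.95, drop_sd)
        cur_j = np.exp(kappa * cur_log + (1.0 - kappa) * (
            _ar1(rng, n, 0.98, cur_sd) + cur_log.mean()))
        u_frac = _copula_uniform(shared_z_frac, rng.standard_normal(n_days), kappa)
        u_alloc = _copula_uniform(shared_z_alloc, rng.standard_normal(n), kappa)
        alloc_noise = -np.log1p(-np.clip(u_alloc, 0.0, 1 - 1e-12))  # Exp(1)

        m = 1.0
        if config.zero_inflation_target > 0:
            m = _calibrate_trigger_scale(
                drop_j, cur_j, day_idx,
                config.pressure_trigger, config.current_trigger,
                config.zero_inflation_target)
        p_thr = m * config.pressure_trigger
        c_thr = m * config.current_trigger
        excess = (np.clip(drop_j - p_thr, 0.0, None) / p_thr
                  + np.clip(cur_j - c_thr, 0.0, None) / c_thr)
        # low absolute pressure amplifies the vented share (bubbles expand
        # and gain buoyancy), but never opens the vent on its own: the
        # amplification multiplies the threshold-gated excess
        atm = drivers.atm_pressure.values
        p_sd = atm.std() or 1.0
        low_p = np.clip((np.median(atm) - atm) / p_sd, 0.0, None)
        excess = excess * (1.0 + low_p)

        weights = excess * alloc_noise
        storage = config.initial_storage_fraction * config.storage_capacity
        flux = np.zeros(n)
        day_starts = np.searchsorted(day_idx, np.arange(n_days))
        day_ends = np.append(day_starts[1:], n)

        # daily released fraction: Beta-distributed around a mean that scales
        # with the day's integrated trigger excess (stronger forcing vents a
        # larger share of the store); the coefficient of variation is fixed
        # by the configured mean/sd
        e_day = np.add.reduceat(excess, day_starts)
        pos = e_day[e_day > 0]
        e_ref = pos.mean() if pos.size else 1.0
        cv = config.release_fraction_sd / config.release_fraction_mean
        # saturating response: mean fraction equals the configured mean at the
        # reference intensity and at most doubles for extreme forcing
        mean_d = np.clip(2.0 * config.release_fraction_mean
                         * e_day / (e_ref + e_day), 1e-4, 0.6)
        sd_d = cv * mean_d
        nu = np.clip(mean_d * (1.0 - mean_d) / sd_d**2 - 1.0, 0.05, None)
        frac_day = stats.beta.ppf(u_frac, mean_d * nu, (1.0 - mean_d) * nu)
        for d in range(n_days):
            s0, s1 = day_starts[d], day_ends[d]
            w = weights[s0:s1]
            wsum = w.sum()
            day_release = frac_day[d] * storage if wsum > 0 else 0.0
            for i in range(s0, s1):
                storage += production[i] * delta
                r = 0.0
                if day_release > 0:
                    r = min(day_release * weights[i] / wsum, storage)
                if storage - r > config.storage_capacity:
                    r = storage - config.storage_capacity  # overflow vents
                storage -= r
                flux[i] = r / delta
        site = f"P{j + 1}"
        ch4 = RegularSeries(start=grid[0], interval=step, values=flux,
                            units="mg CH4 m-2 d-1", name=f"{site}_ch4_flux")
        # equivalent bubble volume at STP from the methane mass
        mol = flux * 1e-3 / 16.04 / 0.689
        gas = mol * 8.314462618 * STANDARD_TEMPERATURE / STANDARD_PRESSURE * 1e6
        gas_series = RegularSeries(start=grid[0], interval=step, values=gas,
                                   units="mL m-2 d-1", name=f"{site}_gas_flux")
        out.append(FluxSeries(site=site, gas_flux=gas_series, methane_flux=ch4,
                              meta={"kappa": kappa, "seed": config.seed, "site_index": j}))
    return out


def gen_abt_records(
    flux: FluxSeries,
    cal: CalibrationSpec,
    ambient: DriverBundle,
    rng: np.random.Generator | None = None,
    height_noise_sd: float = 0.0,
) -> RawABTLog:
    """Invert the flux computation into a 30-s fill-height log.

    The STP gas flux is spread evenly over the 30-s steps of each base
    interval, converted to in-situ volume at the trap (temperature from the
    surface series, pressure = atmospheric + hydrostatic at trap depth) and
    accumulated as fill height.  The valve flushes at ``cal.max_fill_height``
    and every ``cal.flush_period``; optional Gaussian height noise emulates
    sensor jitter.
    """
    gas = flux.gas_flux
    if np.isnan(gas.values).any():
        raise ValueError("gen_abt_records: flux series contains missing values")
    if (gas.values < 0).any():
        raise ValueError("gen_abt_records: negative fluxes are not physical")

    step30 = pd.Timedelta(seconds=30)
    t30 = pd.date_range(gas.index[0] - gas.interval + step30, gas.index[-1], freq=step30)
    per = int(gas.interval / step30)
    flux30 = np.repeat(gas.values, per)  # mL m-2 d-1, constant within interval

    # ambient conditions at the trap, interpolated to the 30-s grid
    trap_depth = ambient.meta.get("trap_depth", 2.0)
    temp_k = np.interp(t30.asi8.astype(float), ambient.temp_surface.index.asi8.astype(float),
                       ambient.temp_surface.values) + 273.15
    p_pa = np.interp(t30.asi8.astype(float), ambient.atm_pressure.index.asi8.astype(float),
                     ambient.atm_pressure.values) * 1e3 + WATER_DENSITY * GRAVITY * trap_depth

    v_stp = flux30 * cal.funnel_area * (30.0 / SECONDS_PER_DAY) / 1e6  # m3 per step
    v_insitu = v_stp * (cal.standard_pressure / p_pa) * (temp_k / cal.standard_temperature)
    dh = v_insitu / cal.tube_cross_section

    n = len(t30)
    height = np.empty(n)
    flushed = np.zeros(n, dtype=bool)
    h = 0.0
    next_flush = t30[0] + cal.flush_period
    for i in range(n):
        h += dh[i]
        if h >= cal.max_fill_height or t30[i] >= next_flush:
            # valve opens at the start of the step: the previously
            # accumulated gas is vented, gas arriving during the flush step
            # stays in the tube and appears in the next record's increment
            flushed[i] = True
            next_flush = t30[i] + cal.flush_period
            height[i] = 0.0
            h = dh[i]
        else:
            height[i] = h
    if rng is not None and height_noise_sd > 0:
        height = np.clip(height + rng.standard_normal(n) * height_noise_sd, 0.0, None)

    return RawABTLog(
        timestamps=t30, fill_height=height,
        temperature_c=temp_k - 273.15, pressure_kpa=p_pa / 1e3,
        flush_flag=flushed, site=flux.site,
    )
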