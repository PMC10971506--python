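"""Time-series preparation: regular grids, aggregation, station merging,
velocity statistics.

Raw sensor records arrive at assorted native cadences and phases.  The
pipeline first builds high-resolution regular tables (5/10 min) by linear
interpolation onto predefined end-of-interval timestamps, then averages the
10-min tables up to hourly/daily/weekly resolution.  Coarse-native variables
(e.g. daily chlorophyll-a) are never downscaled: inventing sub-daily
structure would contaminate the spectral and coherence analyses downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .timeseries import RegularSeries, as_interval


def regularize(
    raw: pd.Series,
    interval: str | pd.Timedelta,
    max_gap: pd.Timedelta | None = None,
    units: str = "",
    name: str | None = None,
    start: pd.Timestamp | None = None,
    end: pd.Timestamp | None = None,
) -> RegularSeries:
    """Linearly interpolate an irregular series onto a fixed grid.

    Grid timestamps mark the end of each interval and are aligned to whole
    multiples of ``interval`` within the day.  A grid point is masked when
    either bracketing raw sample is farther than ``max_gap`` away (default:
    3 grid intervals), so interpolation never bridges long outages.
    """
    if len(raw) == 0:
        raise ValueError("regularize: empty input series")
    raw = raw.dropna()
    if len(raw) == 0:
        raise ValueError("regularize: input series has no valid samples")
    idx = pd.DatetimeIndex(raw.index)
    if not idx.is_monotonic_increasing:
        raise ValueError("regularize: raw timestamps must be increasing")
    step = as_interval(interval)
    if max_gap is None:
        max_gap = 3 * step

    t0 = pd.Timestamp(start) if start is not None else idx[0].ceil(step)
    t1 = pd.Timestamp(end) if end is not None else idx[-1].floor(step)
    if t1 < t0:
        raise ValueError("regularize: no grid points inside the data range")
    grid = pd.date_range(t0, t1, freq=step)

    tr = idx.asi8.astype(float)
    tg = grid.asi8.astype(float)
    vals = np.interp(tg, tr, raw.to_numpy(dtype=float))

    # distance to nearest raw sample on each side; inf when unbracketed
    pos = np.searchsorted(tr, tg)
    left = np.where(pos > 0, tg - tr[np.maximum(pos - 1, 0)], np.inf)
    right = np.where(pos < len(tr), tr[np.minimum(pos, len(tr) - 1)] - tg, np.inf)
    on_sample = np.isin(tg, tr)
    gap_ns = float(max_gap.value)
    vals[~on_sample & ((left > gap_ns) | (right > gap_ns))] = np.nan

    return RegularSeries(
        start=grid[0], interval=step, values=vals, units=units,
        name=name if name is not None else (raw.name or "value"),
    )


def aggregate(
    series: RegularSeries,
    target: str | pd.Timedelta,
    min_valid_fraction: float = 0.5,
) -> RegularSeries:
    """Average a fine series up to a coarser interval.

    The coarse sample stamped ``t`` is the mean of fine samples in
    ``(t - target, t]`` (end-of-interval convention preserved).  Windows with
    fewer than ``min_valid_fraction`` valid members are masked.  Downscaling
    (target finer than source) is rejected.
    """
    step = as_interval(target)
    ratio = step / series.interval
    if step < series.interval:
        raise ValueError("aggregate: downscaling to a finer interval is not supported")
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("aggregate: target must be an integer multiple of the source interval")
    k = int(round(ratio))
    if k == 1:
        return series.copy()

    # end-of-interval bins: window (t - target, t] is labeled t; bins are
    # anchored at midnight of the first day, so hourly/daily products align
    # with clock hours/days and weekly products are 7-day blocks from the
    # series' first day
    s = series.to_pandas()
    grouped = s.resample(step, closed="right", label="right", origin="start_day")
    means = grouped.mean()
    counts = grouped.count()
    means[counts < min_valid_fraction * k] = np.nan

    return RegularSeries(
        start=means.index[0], interval=step, values=means.to_numpy(),
        units=series.units, name=series.name,
    )


def merge_stations(
    primary: RegularSeries,
    secondary: RegularSeries,
    min_overlap: int = 48,
) -> tuple[RegularSeries, np.ndarray]:
    """Fill gaps in ``primary`` with linearly transformed ``secondary`` data.

    An OLS fit ``primary ~ a + b * secondary`` over the overlapping valid
    samples maps the secondary station onto the primary one; only the
    primary's missing samples are replaced.  Returns the merged series and a
    boolean array flagging filled points.  Valid primary data are never
    overwritten.
    """
    from .timeseries import require_same_grid

    require_same_grid(primary, secondary)
    both = ~primary.mask & ~secondary.mask
    n_pairs = int(both.sum())
    if n_pairs < min_overlap:
        raise ValueError(
            f"merge_stations: only {n_pairs} overlapping valid pairs "
            f"(need at least {min_overlap})"
        )
    x = secondary.values[both]
    y = primary.values[both]
    slope, intercept = np.polyfit(x, y, 1)

    fill = primary.mask & ~secondary.mask
    merged = primary.values.copy()
    merged[fill] = intercept + slope * secondary.values[fill]
    out = primary.copy(values=merged)
    out.meta = dict(primary.meta, merge_slope=float(slope), merge_intercept=float(intercept))
    return out, fill


def velocity_variance(
    speed: RegularSeries,
    window: str | pd.Timedelta,
    min_valid_fraction: float = 0.5,
) -> RegularSeries:
    """Windowed variance (population convention) of the mean flow speed.

    Horizontal-current variance is only meaningful at windows of one hour or
    longer given the profiler's averaging interval; shorter requests raise.
    """
    step = as_interval(window)
    if step < pd.Timedelta(hours=1):
        raise ValueError("velocity_variance: windows below 1 h are not supported for currents")
    return _windowed_moment(speed, step, min_valid_fraction, stat="var")


def rms_fluctuation(
    velocity: RegularSeries,
    window: str | pd.Timedelta,
    min_valid_fraction: float = 0.5,
) -> RegularSeries:
    """RMS of deviations from the window mean (turbulent fluctuation scale)."""
    return _windowed_moment(velocity, as_interval(window), min_valid_fraction, stat="rms")


def _windowed_moment(series, step, min_valid_fraction, stat):
    ratio = step / series.interval
    if abs(ratio - round(ratio)) > 1e-9 or step < series.interval:
        raise ValueError("window must be an integer multiple of the native interval")
    k = int(round(ratio))
    vals = series.values
    pad_tail = (-len(vals)) % k
    padded = np.concatenate([vals, np.full(pad_tail, np.nan)])
    blocks = padded.reshape(-1, k)
    valid = ~np.isnan(blocks)
    counts = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.where(valid, blocks, 0.0), axis=1) / counts
        dev2 = np.where(valid, (blocks - means[:, None]) ** 2, 0.0)
        var = dev2.sum(axis=1) / counts  # population (1/n) convention
    var[counts < min_valid_fraction * k] = np.nan
    out_vals = var if stat == "var" else np.sqrt(var)
    units = f"({series.units})^2" if stat == "var" else series.units
    name = f"{series.name}_{'variance' if stat == 'var' else 'rms'}"
    return RegularSeries(
        start=series.index[k - 1], interval=step, values=out_vals,
        units=units, name=name,
    )
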