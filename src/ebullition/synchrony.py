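"""Multi-site synchronization of daily ebullition via the Kuramoto order
parameter.

Each site's daily flux series is treated as an oscillator: short gaps are
filled by linear interpolation (up to 8 consecutive points — longer outages
make the window unusable), the linear trend is removed, the series is
z-scored, and the instantaneous phase is taken from the analytic signal
(Hilbert transform).  The order parameter

    r(t) = | (1/N) * sum_j exp(i * theta_j(t)) |

is 1 when all sites oscillate in phase and 0 for perfectly opposing phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend, hilbert

from .timeseries import RegularSeries, require_same_grid

MAX_GAP_POINTS = 8


@dataclass
class SynchronyTrace:
    """Kuramoto order parameter r(t) over a common daily grid."""

    r: RegularSeries
    mean_r: float
    sd_r: float
    weekly_mean_r: RegularSeries
    sites: tuple[str, ...]


def fill_short_gaps(values: np.ndarray, max_gap: int = MAX_GAP_POINTS) -> np.ndarray:
    """Linear interpolation of interior gaps up to ``max_gap`` points.

    Longer gaps (or missing edges) raise: the Kuramoto analysis requires a
    continuous window and the caller must choose one.
    """
    v = np.asarray(values, dtype=float).copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    if isnan.all():
        raise ValueError("series is entirely missing")
    if isnan[0] or isnan[-1]:
        raise ValueError("series starts or ends with missing values; trim the window")
    # locate runs of NaN
    edges = np.flatnonzero(np.diff(isnan.astype(int)))
    starts = edges[::2] + 1
    ends = edges[1::2] + 1  # exclusive
    for s, e in zip(starts, ends):
        if e - s > max_gap:
            raise ValueError(
                f"gap of {e - s} points at index {s} exceeds the "
                f"{max_gap}-point interpolation limit"
            )
    idx = np.arange(v.size)
    v[isnan] = np.interp(idx[isnan], idx[~isnan], v[~isnan])
    return v


def phase_preprocess(series: RegularSeries, max_gap: int = MAX_GAP_POINTS) -> np.ndarray:
    """Instantaneous phase (radians) after gap-fill, detrend and z-scoring."""
    v = fill_short_gaps(series.values, max_gap=max_gap)
    if np.ptp(v) == 0:
        raise ValueError(f"series {series.name!r} has zero variance; phase undefined")
    v = detrend(v, type="linear")
    sd = v.std()
    if sd < 1e-12 * (np.abs(v).max() + 1.0):
        raise ValueError(f"series {series.name!r} has zero variance after detrending")
    v = (v - v.mean()) / sd
    return np.angle(hilbert(v))


def kuramoto_r(
    phases: list[np.ndarray],
    edge_fraction: float = 0.05,
) -> tuple[np.ndarray, float, float]:
    """Order parameter r(t) from per-site phase sequences.

    Returns ``(r, mean_r, sd_r)`` where the mean/sd exclude the first and
    last ``edge_fraction`` of samples (analytic-signal edge distortion).
    """
    if len(phases) < 2:
        raise ValueError("kuramoto_r needs at least two sites")
    lengths = {len(p) for p in phases}
    if len(lengths) != 1:
        raise ValueError("phase sequences are not on a common grid")
    theta = np.vstack(phases)
    r = np.abs(np.exp(1j * theta).mean(axis=0))
    n = r.size
    k = int(np.floor(edge_fraction * n))
    core = r[k: n - k] if k else r
    return r, float(core.mean()), float(core.std())


def synchrony_trace(
    sites: list[RegularSeries],
    edge_fraction: float = 0.05,
    max_gap: int = MAX_GAP_POINTS,
) -> SynchronyTrace:
    """End-to-end synchrony of same-grid daily flux series."""
    require_same_grid(*sites)
    phases = [phase_preprocess(s, max_gap=max_gap) for s in sites]
    r, mean_r, sd_r = kuramoto_r(phases, edge_fraction=edge_fraction)
    r_series = sites[0].copy(values=r, units="-", name="kuramoto_r")
    from .prep import aggregate

    weekly = aggregate(r_series, pd.Timedelta(weeks=1))
    return SynchronyTrace(
        r=r_series, mean_r=mean_r, sd_r=sd_r,
        weekly_mean_r=weekly, sites=tuple(s.name for s in sites),
    )
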