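"""Spectral and wavelet analysis of flux and driver series.

Three views of where the variance of a series lives:

* :func:`welch_spectrum` — averaged modified periodograms (Hamming window,
  50 % overlap), rendered variance-preserving as ``f * S(f)`` so equal areas
  on a log-frequency axis carry equal variance.
* :func:`cwt_scalogram` — continuous wavelet transform with a generalized
  Morse wavelet, localizing periodic components in time.
* :func:`wavelet_coherence` — magnitude-squared coherence between two series
  from smoothed Morlet cross- and auto-wavelet spectra, with the phase lag of
  one series behind the other expressed as a cycle fraction.

All wavelet results carry a cone of influence (COI): scales closer to the
series edges than the wavelet footprint are flagged unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .timeseries import RegularSeries


@dataclass
class Spectrum:
    frequency: np.ndarray          # Hz
    power: np.ndarray              # density, units^2 / Hz
    variance_preserving: np.ndarray  # f * S(f)
    window: str
    segment_length: int
    overlap: float

    def total_power(self) -> float:
        """Integral of S(f) df — approximately the series variance."""
        return float(np.trapezoid(self.power, self.frequency))


@dataclass
class Scalogram:
    times: pd.DatetimeIndex
    periods: np.ndarray            # seconds, log-spaced
    magnitude: np.ndarray          # |W|, shape (n_periods, n_times)
    coi_period: np.ndarray         # per-time maximum resolved period (s)

    @property
    def outside_coi(self) -> np.ndarray:
        """True where the scale is unresolved (edge-affected)."""
        return self.periods[:, None] > self.coi_period[None, :]


@dataclass
class CoherenceMap:
    times: pd.DatetimeIndex
    periods: np.ndarray
    coherence: np.ndarray          # squared coherence in [0, 1]
    phase: np.ndarray              # radians; phase of x relative to y
    coi_period: np.ndarray

    @property
    def outside_coi(self) -> np.ndarray:
        return self.periods[:, None] > self.coi_period[None, :]

    @property
    def phase_cycles(self) -> np.ndarray:
        """Phase lag mapped to cycle fraction in [0, 1)."""
        return np.mod(self.phase / (2 * np.pi), 1.0)


# ---------------------------------------------------------------------------
# Welch spectra
# ---------------------------------------------------------------------------

def welch_spectrum(
    series: RegularSeries,
    segment_length: int | None = None,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch power spectral density with a Hamming window.

    ``segment_length`` defaults to one eighth of the series length rounded
    down to a power of two.  The input must be gap-free; the linear trend is
    removed per segment.
    """
    x = series.values
    if np.isnan(x).any():
        raise ValueError("welch_spectrum: series contains masked values; split first")
    n = x.size
    if segment_length is None:
        segment_length = max(8, 2 ** int(np.floor(np.log2(max(n // 8, 8)))))
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds series length {n}")
    fs = 1.0 / series.interval.total_seconds()
    freq, psd = sps.welch(
        x, fs=fs, window="hamming", nperseg=segment_length,
        noverlap=int(round(overlap * segment_length)), detrend="linear",
    )
    return Spectrum(
        frequency=freq, power=psd, variance_preserving=freq * psd,
        window="hamming", segment_length=segment_length, overlap=overlap,
    )


# ---------------------------------------------------------------------------
# Continuous wavelet transforms (analytic wavelets, frequency domain)
# ---------------------------------------------------------------------------

def _morse_freq(omega: np.ndarray, beta: float, gamma: float) -> np.ndarray:
    """Generalized Morse wavelet in the frequency domain (positive omega)."""
    peak = (beta / gamma) ** (1.0 / gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnpsi = beta * np.log(omega / peak) - (omega**gamma - peak**gamma) / 1.0
    psi = np.where(omega > 0, 2.0 * np.exp(np.where(omega > 0, lnpsi, 0.0)), 0.0)
    return psi


def _morlet_freq(omega: np.ndarray, omega0: float) -> np.ndarray:
    psi = 2.0 * np.pi**-0.25 * np.exp(-0.5 * (omega - omega0) ** 2)
    return np.where(omega > 0, psi, 0.0)


def _period_grid(n: int, dt: float, voices_per_octave: int = 12,
                 min_period: float | None = None,
                 max_period: float | None = None) -> np.ndarray:
    lo = min_period if min_period is not None else 2.0 * dt
    hi = max_period if max_period is not None else n * dt / 2.0
    n_oct = np.log2(hi / lo)
    m = max(2, int(np.ceil(n_oct * voices_per_octave)) + 1)
    return lo * 2.0 ** (np.arange(m) * n_oct / (m - 1))


def _cwt(x: np.ndarray, dt: float, periods: np.ndarray, wavelet: str,
         morse_beta: float = 20.0, morse_gamma: float = 3.0,
         morlet_omega0: float = 6.0) -> tuple[np.ndarray, float]:
    """Analytic CWT over the given Fourier periods.

    Returns (W, efold) with W of shape (n_periods, n), and ``efold`` the
    e-folding factor converting a distance-to-edge into the maximum resolved
    Fourier period (COI slope).
    """
    n = x.size
    xhat = np.fft.fft(x - x.mean())
    omega_k = 2.0 * np.pi * np.fft.fftfreq(n, d=dt)

    if wavelet == "morse":
        peak = (morse_beta / morse_gamma) ** (1.0 / morse_gamma)
        scales = periods * peak / (2.0 * np.pi)

        def mother(so):
            return _morse_freq(so, morse_beta, morse_gamma)
    elif wavelet == "morlet":
        w0 = morlet_omega0
        fourier_factor = 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0**2))
        scales = periods / fourier_factor

        def mother(so):
            return _morlet_freq(so, w0)
    else:
        raise ValueError(f"unknown wavelet {wavelet!r}")

    W = np.empty((periods.size, n), dtype=complex)
    for i, s in enumerate(scales):
        W[i] = np.fft.ifft(xhat * mother(s * omega_k))
    # COI: edge influence extends sqrt(2) scales; expressed as max period per
    # distance d from the nearest edge: P_max(d) = d * (period/scale) / sqrt(2)
    efold = float(periods[0] / scales[0] / np.sqrt(2.0))
    return W, efold


def _coi_period(n: int, dt: float, efold: float) -> np.ndarray:
    d = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    return d * efold


def cwt_scalogram(
    series: RegularSeries,
    wavelet: str = "morse",
    voices_per_octave: int = 12,
    min_period: pd.Timedelta | None = None,
    max_period: pd.Timedelta | None = None,
) -> Scalogram:
    """|CWT| magnitude over a logarithmic period grid, with COI."""
    x = series.values
    if np.isnan(x).any():
        raise ValueError("cwt_scalogram: series contains masked values; split first")
    dt = series.interval.total_seconds()
    periods = _period_grid(
        x.size, dt, voices_per_octave,
        None if min_period is None else min_period.total_seconds(),
        None if max_period is None else max_period.total_seconds(),
    )
    W, efold = _cwt(x, dt, periods, wavelet)
    return Scalogram(
        times=series.index, periods=periods, magnitude=np.abs(W),
        coi_period=_coi_period(x.size, dt, efold),
    )


def _smooth(W: np.ndarray, scales_in_samples: np.ndarray,
            time_factor: float = 2.0, scale_window: int = 7) -> np.ndarray:
    """Boxcar smoothing in time (width ~ ``time_factor`` scales) and a
    boxcar across ``scale_window`` neighbouring scales (~half an octave at
    the default 12 voices per octave)."""
    out = np.empty_like(W)
    for i, w in enumerate(scales_in_samples):
        width = max(3, int(round(time_factor * w)))
        kernel = np.ones(width) / width
        re = np.convolve(W[i].real, kernel, mode="same")
        if np.iscomplexobj(W):
            im = np.convolve(W[i].imag, kernel, mode="same")
            out[i] = re + 1j * im
        else:
            out[i] = re
    k = min(scale_window, out.shape[0])
    if k >= 2:
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.pad(out, ((pad, pad), (0, 0)), mode="edge")
        sm = np.empty_like(out)
        for j in range(out.shape[0]):
            sm[j] = padded[j: j + k].mean(axis=0)
        out = sm
    return out


def wavelet_coherence(
    x: RegularSeries,
    y: RegularSeries,
    wavelet: str = "morlet",
    voices_per_octave: int = 12,
    min_period: pd.Timedelta | None = None,
    max_period: pd.Timedelta | None = None,
) -> CoherenceMap:
    """Squared wavelet coherence and phase lag between two series.

    Smoothing of the cross- and auto-spectra in time and scale is essential:
    without it the coherence is identically 1.  The phase is the argument of
    the smoothed cross-spectrum ``Wx * conj(Wy)``; a positive phase means
    ``x`` leads ``y``.
    """
    from .timeseries import require_same_grid

    if len(x) != len(y):
        raise ValueError("wavelet_coherence: series lengths differ")
    require_same_grid(x, y)
    for s in (x, y):
        if np.isnan(s.values).any():
            raise ValueError("wavelet_coherence: series contain masked values")
    dt = x.interval.total_seconds()
    n = len(x)
    periods = _period_grid(
        n, dt, voices_per_octave,
        None if min_period is None else min_period.total_seconds(),
        None if max_period is None else max_period.total_seconds(),
    )
    Wx, efold = _cwt(x.values, dt, periods, wavelet)
    Wy, _ = _cwt(y.values, dt, periods, wavelet)

    # scale-normalized spectra, then smoothing in time and scale
    inv_s = (1.0 / periods)[:, None]
    cross = _smooth(Wx * np.conj(Wy) * inv_s, periods / dt)
    sxx = _smooth(np.abs(Wx) ** 2 * inv_s, periods / dt)
    syy = _smooth(np.abs(Wy) ** 2 * inv_s, periods / dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(cross) ** 2 / (sxx * syy)
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    return CoherenceMap(
        times=x.index, periods=periods, coherence=coh,
        phase=np.angle(cross), coi_period=_coi_period(n, dt, efold),
    )


def phase_to_lag(phase_cycles: float, period: pd.Timedelta | float) -> pd.Timedelta | float:
    """Convert a phase lag in cycle fractions to a time delay.

    ``phase_to_lag(3/8, 60 h) == 22.5 h``: at a 60-hour period, a 3/8-cycle
    phase arrow means the lagging series responds 22.5 hours later.
    """
    phase_cycles = np.asarray(phase_cycles, dtype=float)
    if np.any((phase_cycles < 0) | (phase_cycles >= 1)):
        raise ValueError("phase must be given as a cycle fraction in [0, 1)")
    out = phase_cycles * period
    if np.ndim(phase_cycles) == 0:
        return phase_cycles.item() * period
    return out


def coherence_long_table(cmap: CoherenceMap) -> pd.DataFrame:
    """Long-format (time, period, coherence, phase, in_coi) table for export."""
    return pd.DataFrame({
        "timestamp": cmap.times.repeat(cmap.periods.size),
        "period_s": np.tile(cmap.periods, len(cmap.times)),
        "coherence": cmap.coherence.T.ravel(),
        "phase_cycles": cmap.phase_cycles.T.ravel(),
        "resolved": ~cmap.outside_coi.T.ravel(),
    })
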