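"""Freshwater density, relative water column stability (RWCS) and mixing regime.

RWCS measures the thermal resistance of the water column to mixing:

    RWCS = (rho_bottom - rho_surface) / (rho_4C - rho_5C)

where densities come from the UNESCO (1981) equation of state for pure water
(salinity 0, surface pressure).  The denominator — the density difference of
water between 4 and 5 degC — makes the index dimensionless and comparable
across systems.  Classification thresholds: RWCS < 16.3 mixed, RWCS > 56.5
stratified, in between partially stratified (boundary values are assigned to
"partial": the thresholds are strict inequalities).
"""

from __future__ import annotations

import numpy as np

# UNESCO (1981) / EOS-80 pure-water density polynomial coefficients (kg m-3),
# evaluated at salinity 0 and atmospheric pressure.
_UNESCO_COEFFS = (
    999.842594,
    6.793952e-2,
    -9.095290e-3,
    1.001685e-4,
    -1.120083e-6,
    6.536332e-9,
)

REGIME_MIXED = "mixed"
REGIME_PARTIAL = "partial"
REGIME_STRATIFIED = "stratified"

RWCS_MIXED_BELOW = 16.3
RWCS_STRATIFIED_ABOVE = 56.5


def unesco_density(temp_c):
    """Pure-water density (kg m-3) at temperature ``temp_c`` (degC).

    Valid for 0 <= T <= 40 degC; out-of-range temperatures raise ValueError
    (NaN inputs propagate as NaN).
    """
    t = np.asarray(temp_c, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (t < 0.0) | (t > 40.0)
    if np.any(bad):
        raise ValueError("temperature outside the 0-40 degC validity range")
    rho = np.zeros_like(t)
    for k, c in enumerate(_UNESCO_COEFFS):
        rho = rho + c * t**k
    return rho if rho.ndim else float(rho)


# Denominator of the stability index: density difference across the 4-5 degC
# interval where freshwater density peaks.
_RWCS_DENOM = unesco_density(4.0) - unesco_density(5.0)


def rwcs(temp_bottom_c, temp_surface_c):
    """Relative water column stability from bottom/surface temperature (degC)."""
    rho_b = unesco_density(temp_bottom_c)
    rho_s = unesco_density(temp_surface_c)
    out = (rho_b - rho_s) / _RWCS_DENOM
    return out if np.ndim(out) else float(out)


def classify_regime(rwcs_value):
    """Map RWCS to 'mixed' (< 16.3), 'stratified' (> 56.5) or 'partial'.

    Vectorized; returns a str for scalar input, object array otherwise.
    NaN maps to the empty string (missing).
    """
    x = np.asarray(rwcs_value, dtype=float)
    out = np.full(x.shape, REGIME_PARTIAL, dtype=object)
    with np.errstate(invalid="ignore"):
        out[x < RWCS_MIXED_BELOW] = REGIME_MIXED
        out[x > RWCS_STRATIFIED_ABOVE] = REGIME_STRATIFIED
    out[np.isnan(x)] = ""
    if x.ndim == 0:
        return str(out[()])
    return out


def stratification_table(temp_bottom, temp_surface):
    """RWCS + regime labels for paired bottom/surface temperature series.

    Accepts two same-grid :class:`~ebullition.timeseries.RegularSeries` and
    returns ``(rwcs_series, regime_labels)``.
    """
    from .timeseries import require_same_grid

    require_same_grid(temp_bottom, temp_surface)
    vals = rwcs(temp_bottom.values, temp_surface.values)
    series = temp_bottom.copy(values=np.asarray(vals), units="-", name="rwcs")
    return series, classify_regime(vals)
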