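"""Bubble-trap log processing: segmentation, gas standardization, fluxes.

Derived expected values were computed by hand from the ideal gas law before
the module was written (see inline comments).
"""

import numpy as np
import pandas as pd
import pytest

from ebullition.abt import (CalibrationSpec, RawABTLog, flux_series,
                            methane_mass, process_log, segment_flushes,
                            standardize_volume)


@pytest.fixture
def cal():
    return CalibrationSpec(tube_cross_section=1e-3)


def make_log(heights, flush=None, temp=20.0, pressure=101.325, start="2019-01-01", site="P1"):
    n = len(heights)
    flags = np.zeros(n, dtype=bool)
    if flush is not None:
        flags[list(flush)] = True
    return RawABTLog(
        timestamps=pd.date_range(start, periods=n, freq="30s"),
        fill_height=np.asarray(heights, dtype=float),
        temperature_c=np.full(n, temp), pressure_kpa=np.full(n, pressure),
        flush_flag=flags, site=site)


class TestStandardizeVolume:
    def test_identity_at_standard_state(self, cal):
        assert standardize_volume(100.0, 293.15, 101325.0, cal) == pytest.approx(100.0)

    def test_doubled_pressure_doubles_volume(self, cal):
        assert standardize_volume(100.0, 293.15, 202650.0, cal) == pytest.approx(200.0)

    def test_hand_computed_oracle(self, cal):
        # 100 mL * (111325/101325) * (293.15/288.15) = 111.7757 mL
        expected = 100.0 * (111325.0 / 101325.0) * (293.15 / 288.15)
        assert standardize_volume(100.0, 288.15, 111325.0, cal) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(111.7757, abs=1e-4)

    def test_monotone_in_pressure_and_temperature(self, cal):
        base = standardize_volume(1.0, 293.15, 101325.0, cal)
        assert standardize_volume(1.0, 293.15, 102000.0, cal) > base
        assert standardize_volume(1.0, 300.0, 101325.0, cal) < base

    def test_rejects_nonpositive_state(self, cal):
        with pytest.raises(ValueError):
            standardize_volume(1.0, -1.0, 101325.0, cal)
        with pytest.raises(ValueError):
            standardize_volume(1.0, 293.15, 0.0, cal)


class TestMethaneMass:
    def test_zero_volume_zero_mass(self, cal):
        assert methane_mass(0.0, 293.15, 101325.0, cal) == 0.0

    def test_hand_computed_oracle(self, cal):
        # n = PV/RT = 101325 * 1e-6 / (8.314462618 * 293.15) = 4.1571e-5 mol
        # mass = n * 0.689 * 16.04 g/mol = 4.5941e-4 g = 0.459 mg
        mass = methane_mass(1e-6, 293.15, 101325.0, cal)
        assert mass == pytest.approx(0.4594, abs=2e-4)

    def test_linear_in_methane_fraction(self):
        lo = CalibrationSpec(methane_fraction=0.3)
        hi = CalibrationSpec(methane_fraction=0.6)
        m_lo = methane_mass(1e-6, 293.15, 101325.0, lo)
        m_hi = methane_mass(1e-6, 293.15, 101325.0, hi)
        assert m_hi == pytest.approx(2.0 * m_lo)

    def test_mass_from_standardized_volume_equals_in_situ_route(self, cal):
        # dimensional consistency: mass from V_std at (P_std, T_std) must
        # equal mass from raw V at in-situ (P, T)
        v, t, p = 3.3e-6, 288.0, 97000.0
        direct = methane_mass(v, t, p, cal)
        v_std = standardize_volume(v, t, p, cal)
        via_std = methane_mass(v_std, cal.standard_temperature, cal.standard_pressure, cal)
        assert via_std == pytest.approx(direct, rel=1e-9)


class TestSegmentFlushes:
    def test_constant_fill_height_gives_zero_increments(self, cal):
        segs = segment_flushes(make_log(np.full(100, 0.2)), cal)
        assert len(segs) == 1
        assert np.allclose(segs[0].volumes_m3, 0.0)

    def test_volume_arithmetic_across_reset(self, cal):
        # 0 -> 0.1 -> 0.2 m, flush, 0 -> 0.1 m with 1e-3 m2 tube = 300 mL
        log = make_log([0.0, 0.1, 0.2, 0.0, 0.1], flush=[3])
        segs = segment_flushes(log, cal)
        total = sum(s.volumes_m3.sum() for s in segs)
        assert total == pytest.approx(300e-6)
        assert len(segs) == 2

    def test_jitter_clipped_but_large_drops_flagged(self, cal):
        log = make_log([0.0, 0.1, 0.0995, 0.2, 0.1, 0.15])  # -0.5 mm jitter, -100 mm fault
        segs = segment_flushes(log, cal)
        assert all((s.volumes_m3 >= 0).all() for s in segs)
        assert sum(s.fault_mask.sum() for s in segs) == 1  # fault recorded, not dropped
        assert len(segs) == 2  # the big unflagged drop splits the log

    def test_round_trip_segment_count_matches_generated_flushes(self, small_config,
                                                                small_drivers, small_fluxes):
        from ebullition import CalibrationSpec, gen_abt_records

        cal = CalibrationSpec()
        log = gen_abt_records(small_fluxes[0], cal, small_drivers)
        segs = segment_flushes(log, cal)
        assert len(segs) == int(log.flush_flag.sum()) + 1


class TestFluxSeries:
    def test_ten_ml_over_a_day_yields_expected_flux(self, cal):
        # 10 mL STP in one day over 0.78 m2 -> 10 / 0.78 = 12.82 mL m-2 d-1
        n = 2880
        heights = np.linspace(0.0, 0.01, n)  # 10 mL via 1e-3 m2 tube
        log = make_log(heights)
        out = flux_series(segment_flushes(log, cal), cal, "1d",
                          span=(pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-02")))
        assert out.gas_flux.values[0] == pytest.approx(10.0 / 0.78, rel=1e-3)

    def test_zero_accumulation_is_a_valid_zero(self, cal):
        log = make_log(np.zeros(2880))
        out = flux_series(segment_flushes(log, cal), cal, "1d",
                          span=(pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-02")))
        assert out.gas_flux.values[0] == 0.0
        assert not out.gas_flux.mask[0]

    def test_poor_coverage_masks_interval(self, cal):
        log = make_log(np.zeros(1000))  # ~8.3 h of records in a 1-d interval
        out = flux_series(segment_flushes(log, cal), cal, "1d",
                          span=(pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-02")))
        assert out.gas_flux.mask[0]

    def test_unsupported_interval_rejected(self, cal):
        log = make_log(np.zeros(100))
        with pytest.raises(ValueError, match="unsupported interval"):
            flux_series(segment_flushes(log, cal), cal, "3h")

    def test_volume_conserved_across_interval_choices(self, cal):
        rng = np.random.default_rng(0)
        increments = rng.exponential(2e-5, 2880).cumsum()
        log = make_log(increments)
        span = (pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-02"))
        daily = flux_series(segment_flushes(log, cal), cal, "1d", span=span)
        hourly = flux_series(segment_flushes(log, cal), cal, "1h", span=span)
        # flux-weighted volume totals agree regardless of the interval
        vol_daily = np.nansum(daily.gas_flux.values) * 0.78 * 1.0
        vol_hourly = np.nansum(hourly.gas_flux.values) * 0.78 / 24.0
        assert vol_hourly == pytest.approx(vol_daily, rel=1e-6)


class TestRawLogValidation:
    def test_negative_fill_height_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_log([-0.1, 0.0])

    def test_non_monotone_timestamps_rejected(self):
        ts = pd.DatetimeIndex(["2019-01-01 00:00:00", "2019-01-01 00:00:00"])
        with pytest.raises(ValueError, match="increasing"):
            RawABTLog(timestamps=ts, fill_height=[0, 0], temperature_c=[20, 20],
                      pressure_kpa=[101, 101], flush_flag=[False, False])


def test_process_log_round_trip_recovers_daily_flux(small_config, small_drivers, small_fluxes):
    """Synthetic flux -> 30-s log -> flux pipeline agrees within 1 %."""
    from ebullition import CalibrationSpec, gen_abt_records
    from ebullition.prep import aggregate

    cal = CalibrationSpec()
    log = gen_abt_records(small_fluxes[0], cal, small_drivers)
    daily = process_log(log, cal, "1d")
    ref = aggregate(small_fluxes[0].methane_flux, "1d")
    a = daily.methane_flux.to_pandas()
    b = ref.to_pandas()
    both = a.notna() & b.notna() & (b > 0)
    rel = (a[both] - b[both]).abs() / b[both]
    assert rel.max() < 0.01
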