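import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebullition.synchrony import (fill_short_gaps, kuramoto_r,
                                  phase_preprocess, synchrony_trace)

from conftest import make_series


def daily_series(values, name="flux"):
    return make_series(values, start="2019-01-01", interval="1d", name=name)


class TestGapFill:
    def test_short_interior_gap_filled_linearly(self):
        v = np.array([1.0, np.nan, 3.0, 4.0])
        np.testing.assert_allclose(fill_short_gaps(v), [1, 2, 3, 4])

    def test_gap_of_exactly_eight_points_is_filled(self):
        v = np.concatenate([[0.0], [np.nan] * 8, [9.0], [10.0]])
        out = fill_short_gaps(v)
        np.testing.assert_allclose(out, np.arange(11.0), rtol=1e-12)

    def test_gap_of_nine_points_rejected(self):
        v = np.concatenate([[0.0], [np.nan] * 9, [10.0]])
        with pytest.raises(ValueError, match="9 points"):
            fill_short_gaps(v)

    def test_missing_edges_rejected(self):
        with pytest.raises(ValueError, match="trim"):
            fill_short_gaps(np.array([np.nan, 1.0, 2.0]))


class TestPhasePreprocess:
    def test_sinusoid_phase_advances_one_tenth_cycle_per_day(self):
        n = 200
        t = np.arange(n)
        s = daily_series(np.sin(2 * np.pi * t / 10.0))
        phases = np.unwrap(phase_preprocess(s))
        rate = np.diff(phases)[40:-40]  # away from analytic-signal edges
        np.testing.assert_allclose(rate, 2 * np.pi / 10.0, atol=0.03)

    def test_linear_trend_removed_before_phase(self):
        n = 200
        t = np.arange(n)
        clean = np.sin(2 * np.pi * t / 10.0)
        trended = clean + 0.05 * t
        p_clean = phase_preprocess(daily_series(clean))
        p_trend = phase_preprocess(daily_series(trended))
        core = slice(20, -20)
        np.testing.assert_allclose(np.unwrap(p_clean)[core], np.unwrap(p_trend)[core],
                                   atol=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            phase_preprocess(daily_series(np.ones(50)))


class TestKuramotoR:
    def test_identical_phases_give_unit_order_parameter(self):
        theta = np.linspace(0, 8 * np.pi, 100)
        r, mean_r, _ = kuramoto_r([theta, theta.copy(), theta.copy()])
        np.testing.assert_allclose(r, 1.0)
        assert mean_r == pytest.approx(1.0)

    def test_two_antiphase_oscillators_cancel(self):
        theta = np.linspace(0, 8 * np.pi, 100)
        r, _, _ = kuramoto_r([theta, theta + np.pi])
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_three_symmetric_phases_cancel(self):
        theta = np.linspace(0, 8 * np.pi, 100)
        r, _, _ = kuramoto_r([theta, theta + 2 * np.pi / 3, theta + 4 * np.pi / 3])
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError, match="two sites"):
            kuramoto_r([np.zeros(10)])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="common grid"):
            kuramoto_r([np.zeros(10), np.zeros(11)])

    @settings(deadline=None, max_examples=20)
    @given(shift=st.floats(-np.pi, np.pi, allow_nan=False))
    def test_invariant_under_common_phase_shift(self, shift):
        rng = np.random.default_rng(0)
        phases = [rng.uniform(-np.pi, np.pi, 50) for _ in range(3)]
        r0, _, _ = kuramoto_r(phases)
        r1, _, _ = kuramoto_r([p + shift for p in phases])
        np.testing.assert_allclose(r0, r1, atol=1e-12)


class TestSynchronyTrace:
    def test_identical_sites_fully_synchronized(self):
        rng = np.random.default_rng(1)
        base = np.abs(rng.normal(10, 5, 140)) * rng.binomial(1, 0.5, 140)
        sites = [daily_series(base.copy(), name=f"P{i}") for i in range(3)]
        trace = synchrony_trace(sites)
        assert trace.mean_r == pytest.approx(1.0)
        assert np.nanmax(trace.weekly_mean_r.values) <= 1.0 + 1e-12

    def test_mean_r_monotone_in_generator_coupling(self):
        """Recovered synchrony rises with the generator's kappa (10 seeds)."""
        from ebullition import SyntheticConfig, gen_drivers, gen_ebullition
        from ebullition.prep import aggregate

        means = {}
        for kappa in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(10):
                cfg = SyntheticConfig(seed=seed, start="2018-12-01", end="2019-04-01",
                                      base_interval="1h", synchrony_kappa=kappa)
                fluxes = gen_ebullition(gen_drivers(cfg), cfg)
                daily = [aggregate(f.methane_flux, "1d") for f in fluxes]
                vals.append(synchrony_trace(daily).mean_r)
            means[kappa] = np.mean(vals)
        assert means[0.0] <= means[0.5] <= means[1.0]
        assert means[1.0] > 0.95
        assert means[0.0] < means[1.0] - 0.2


def test_weekly_rwcs_negatively_associated_with_synchrony():
    """When stratified periods are configured to desynchronize sites, weekly
    synchrony is lower in weeks of higher water-column stability."""
    from scipy import stats as sstats

    from ebullition import SyntheticConfig, gen_drivers, gen_ebullition
    from ebullition.prep import aggregate
    from ebullition.stratification import stratification_table

    rs_vals = []
    for seed in range(5):
        cfg = SyntheticConfig(seed=seed, start="2018-10-01", end="2019-04-01",
                              base_interval="1h", synchrony_kappa=0.9)
        drivers = gen_drivers(cfg)
        rw, _ = stratification_table(drivers.temp_bottom, drivers.temp_surface)
        rw_weekly = aggregate(aggregate(rw, "1d"), "1w")

        # stratification-dependent coupling: strongly stratified weeks use
        # site-specific triggers (kappa low), mixed weeks shared ones
        strat = rw.values > np.nanmedian(rw.values)
        cfg_hi = SyntheticConfig(**{**cfg.__dict__, "synchrony_kappa": 1.0})
        cfg_lo = SyntheticConfig(**{**cfg.__dict__, "synchrony_kappa": 0.0})
        hi = gen_ebullition(drivers, cfg_hi)
        lo = gen_ebullition(drivers, cfg_lo)
        daily = []
        for fh, fl in zip(hi, lo):
            mixed_vals = np.where(strat, fl.methane_flux.values, fh.methane_flux.values)
            daily.append(aggregate(fh.methane_flux.copy(values=mixed_vals), "1d"))
        trace = synchrony_trace(daily)
        weekly_r = trace.weekly_mean_r.to_pandas()
        joined = pd.concat([weekly_r, rw_weekly.to_pandas()], axis=1).dropna()
        rs_vals.append(sstats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic)
    assert np.mean(rs_vals) < 0
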