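# ebullition

Time-series analysis of **methane ebullition** — the episodic transport of
methane from aquatic sediments to the atmosphere by rising bubbles — for
reservoir and lake monitoring campaigns built around automated bubble traps
(ABTs) and high-frequency environmental sensors.

Ebullition is zero-inflated and bursty: most days emit nothing, then a
pressure drop or a near-bed current pulse vents gas accumulated in the
sediment. This package covers the full chain from raw instrument logs to
empirical flux models:

* **Flux computation** — ABT 30-s fill-height logs → flush segmentation →
  ideal-gas standardization (1 atm, 20 °C) → methane mass (68.9 % CH₄ in
  bubbles) → flux series at 5 min…1 d (`ebullition.abt`).
* **Series preparation** — regular end-of-interval grids, linear
  interpolation with gap limits, upscale-only averaging, weather-station
  merging, velocity variance / RMS fluctuation (`ebullition.prep`).
* **Stratification** — UNESCO freshwater density, relative water column
  stability `RWCS = (ρ_bot − ρ_surf)/(ρ_4°C − ρ_5°C)`, mixed / partial /
  stratified classification at 16.3 / 56.5 (`ebullition.stratification`).
* **Synchrony** — multi-site coherence of daily fluxes via the Kuramoto
  order parameter `r(t) = |mean_j e^{iθ_j(t)}|` on analytic-signal phases
  (`ebullition.synchrony`).
* **Spectra and wavelets** — Welch variance-preserving spectra, Morse
  scalograms, Morlet wavelet coherence with phase lags and cone of
  influence (`ebullition.spectral`).
* **Driver statistics** — Kolmogorov–Smirnov normality, Spearman matrices
  (overall and per mixing regime), PCA (`ebullition.driver_stats`).
* **Model suite** — eight literature model forms (refittable), a P-spline
  additive model (GAM) with GCV smoothing and PRESS predicted-R², and the
  evaluation metrics R², RMSE, Nash–Sutcliffe efficiency and the relative
  error of accumulated flux (`ebullition.models`).
* **Synthetic study** — a seeded generator of correlated drivers and
  multi-site, storage-and-trigger ebullition with a tunable inter-site
  coupling κ, used as ground truth throughout the tests
  (`ebullition.synthetic`).

## Worked example

The numbered scripts under `analysis/` walk through the study; each writes
its tables under `results/`. Generating one year of three-site fluxes:

```sh
$ python analysis/01_simulate_study.py --seed 0
synthetic study: 3 sites, 52560 steps at 10min (seed 0)
bottom temperature range: 16.0-23.2 degC
daily methane flux per site (mg CH4 m-2 d-1):
  P1:  40.8 +/-  75.9  median  0.0  zero days 50%  max  611.8  (n=365)
  P2:  40.9 +/-  75.8  median  0.1  zero days 50%  max  429.6  (n=365)
  P3:  40.9 +/-  73.7  median  0.1  zero days 50%  max  413.8  (n=365)
```

Means far above medians, half the days exactly zero, episodic maxima an
order of magnitude above the mean — the signature statistics of field
ebullition records. Pushing the same fluxes through a simulated trap log
and back recovers them:

```sh
$ python analysis/02_flux_from_trap_logs.py --seed 0
trap log: 259200 records at 30 s, 180 flushes, 181 accumulation segments
daily fluxes recovered on 45 non-zero days; max relative error 2.31e-07 (tolerance 1e-2)
```

Synchrony and the model suite:

```sh
$ python analysis/03_stratification_and_synchrony.py --seed 0
mixing regime fractions: {'mixed': '2%', 'partial': '24%', 'stratified': '74%'}
Kuramoto order parameter across 3 sites: mean r = 0.92 +/- 0.14

$ python analysis/06_model_suite.py --seed 0
...
GAM R2 by timescale: {'10min': 0.009, '1h': 0.02, '1d': 0.049, '1w': 0.161}
```

The additive model's skill collapses as temporal resolution increases:
weekly aggregates retain the driver-determined component of release while
10-min series are dominated by the stochastic timing of individual events.
The absolute R² values on synthetic data are deliberately modest — the
generator injects more event-level randomness than a real reservoir — but
the ordering is the robust, transferable result (see `docs/methods.md`).

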