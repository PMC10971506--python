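# Methods

This package analyses the temporal dynamics of methane ebullition — the
episodic transport of methane from aquatic sediments to the atmosphere by
rising bubbles — from automated-bubble-trap (ABT) records and concurrent
environmental time series. Because the pipeline is exercised end to end on a
synthetic study with known ground truth, this note describes both the
analysis methods and what the generator does and does not emulate.

## Flux computation from trap logs (`ebullition.abt`)

An ABT funnels bubbles (0.78 m² opening) into a calibrated tube and logs gas
fill height, gas temperature and pressure every 30 s; a valve flushes the
tube when full or every 12 h. Processing: fill-height differences within
each accumulation segment become per-step gas volumes
(`tube_cross_section · Δh`, clipped at zero); each volume is referred to
standard conditions (1 atm, 20 °C) with the ideal gas law,
`V_std = V · (P/P_std) · (T_std/T)`, and converted to methane mass,
`m = (PV/RT) · f_CH4 · M_CH4`, with a constant bubble methane fraction
f_CH4 = 0.689. Fluxes are sums per fixed interval (5 min…1 d) divided by
funnel area and interval length.

Numerical/QC choices:

* Negative height steps within a 1 mm jitter tolerance are sensor noise and
  clipped to zero; larger unflagged drops split the log and flag the record
  as a fault, which masks the enclosing interval (flagged, never silently
  dropped).
* An interval is valid when ≥ 80 % of its 30-s slots carry records
  (configurable); invalid intervals are masked, never zero-filled. A fully
  covered interval with no accumulation is a genuine zero.
* In-situ (T, P) are taken from the record concurrent with each increment,
  so the standardized-volume and the raw-volume routes to methane mass agree
  to rounding (asserted at 1e-9 relative in the tests).

## Series preparation (`ebullition.prep`)

All analyses run on `RegularSeries`: fixed-interval sequences whose
timestamps mark the **end** of each interval, with NaN as the missing-value
mask. Irregular sensor records are linearly interpolated onto predefined
grid times; a grid point is masked when a bracketing sample is farther than
3 grid intervals away, so interpolation never bridges outages. Coarser
tables are built from the 10-min tables by averaging (window `(t−T, t]`
labelled `t`); windows with under 50 % valid members are masked, and
downscaling is refused — daily-only variables (chlorophyll-a) stay daily.
Weekly products are 7-day blocks anchored at the series' first day. Gappy
weather stations are merged by an OLS fit of the secondary onto the primary
station over their overlap (≥ 48 paired samples); only primary gaps are
filled, and filled points are flagged. Velocity statistics use the
population (1/n) variance convention — each window is treated as the
complete population of that window — and horizontal-current variance is not
defined below 1-h windows.

## Stratification (`ebullition.stratification`)

Relative water column stability:
`RWCS = (ρ_bottom − ρ_surface) / (ρ_4°C − ρ_5°C)`, with densities from the
UNESCO (1981) pure-water polynomial (salinity 0). RWCS < 16.3 is mixed,
RWCS > 56.5 stratified, in between partially stratified; the printed
thresholds are strict inequalities, so boundary values classify as partial.
Bottom water temperature stands in for sediment-surface temperature.

## Synchrony (`ebullition.synchrony`)

Daily flux series per site are made continuous (linear interpolation of
interior gaps up to 8 points — inclusive — longer gaps abort the window),
linearly detrended per analysis window, z-scored, and mapped to
instantaneous phases via the analytic signal (Hilbert transform), the
standard realization of a complex-plane instantaneous phase. The Kuramoto
order parameter `r(t) = |mean_j exp(iθ_j(t))|` is 1 for in-phase and 0 for
perfectly opposing oscillators. Because the analytic signal distorts edges,
the first and last 5 % of samples are excluded from the reported mean ± sd
(configurable).

## Spectral and wavelet analysis (`ebullition.spectral`)

* Welch spectra: Hamming window, 50 % overlap, per-segment linear detrend;
  default segment length is an eighth of the series rounded to a power of
  two. Rendered variance-preserving as `f·S(f)`; `∫S df` recovers the series
  variance within sampling error (±10 % on white-noise fixtures).
* Scalograms use a generalized Morse wavelet (γ = 3, β = 20) evaluated in
  the frequency domain; coherence uses an analytic Morlet (ω₀ = 6). Both are
  FFT-based in-package: the Morse family and direct control over coherence
  smoothing are needed, and the parameterizations are config defaults, not
  field-study claims.
* Wavelet coherence: scale-normalized cross- and auto-spectra smoothed by a
  boxcar of twice the scale in time and 7 neighbouring scales (~half an
  octave at 12 voices/octave), then
  `C² = |S(W_x W_y*)|² / (S(|W_x|²) S(|W_y|²))`. Without smoothing the
  coherence is identically 1. Phase comes from the smoothed cross-spectrum;
  `phase_to_lag` converts cycle fractions to delays (3/8 cycle at a 60-h
  period = 22.5 h). A cone of influence masks scales closer to an edge than
  √2 wavelet e-folding scales; gappy series are analysed per gap-free
  segment.

## Driver statistics (`ebullition.driver_stats`)

Normality is checked with a one-sample Kolmogorov–Smirnov test against a
normal with the sample's mean and sd (α = 0.05); ebullition is zero-inflated
and firmly non-normal, so association uses Spearman rank correlations on
pairwise-complete observations (≥ 10 pairs per cell), reported per cell at
α = 0.05 with no multiple-testing correction across cells — a deliberate
caveat, as each cell is interpreted singly. Regime-conditioned matrices
subset rows by the RWCS classification first. PCA standardizes listwise-
complete rows (correlation-matrix PCA); scores carry regime labels.
Pairwise-complete deletion suits rank correlations; PCA needs complete rows.

## Empirical models (`ebullition.models`)

The registry (`data/literature_models.yml`) holds eight functional forms
from earlier studies of other aquatic systems — binned-temperature
polynomial, modified Arrhenius (`F₂₀·e^{θ(T−20)}`), log-linear temperature
(and temperature + total phosphorus) forms, a weekly autoregressive form, a
linear sediment-properties form, a pressure-threshold form
(`k·max(P_thr − P, 0)`), and a small neural network (one 5-unit tanh hidden
layer, standardized inputs, L-BFGS, fixed seed). Original coefficients are
not shipped; every entry is refittable (`refit_model`: least squares,
nonlinear least squares, or network training) and fixed coefficients can be
supplied by the user. "Change in pressure" predictors are backward first
differences at the model's native timescale. Log-transformed responses use
an offset of half the minimum positive flux, applied and removed
symmetrically, to admit the zero-inflated response.

The additive model is an Eilers–Marx P-spline GAM: each predictor enters
through 10 cubic B-spline basis functions with a second-difference penalty
on the coefficients; one smoothing parameter shared across terms is chosen
by GCV over a 10-point log grid (10⁻³…10⁶). Bases are centred (sum-to-zero)
for identifiability, with a tiny ridge (1e-8 of the mean design diagonal)
absorbing the exact null direction the centring creates. Zero-variance
predictors are dropped with a warning. Because the fit is a linear smoother,
leave-one-out residuals come from the hat diagonal, giving the PRESS-based
predicted R²; values ≤ 0 are reported as 0 and flag overfitting. The model
is cross-checked in the tests against `statsmodels` `GLMGam`.

Evaluation (`evaluate_model`): R² of an OLS fit of observed on predicted
(the headline; identical to squared Pearson correlation for a simple linear
fit), RMSE, Nash–Sutcliffe efficiency `1 − Σ(o−p)²/Σ(o−ō)²`, and the
relative error of accumulated flux `100·(Σo − Σp)/Σo` over stated
continuous-record windows — negative values mean overestimation; a zero
accumulated observed flux leaves it undefined. All metrics are computed on
non-log-transformed fluxes. A constant prediction is reported as R² = 0.

## The synthetic study (`ebullition.synthetic`)

The generator emulates a subtropical, polymictic drinking-water reservoir
monitored for one to three years:

* **Bottom temperature**: seasonal cosine inside 16–23.2 °C (mean 19.6 °C,
  amplitude 3.6 °C, peak around 1 February — southern hemisphere).
* **Stratification**: a non-negative surface–bottom temperature difference
  with seasonal, diurnal and synoptic AR(1) components; bottom dissolved
  oxygen declines with that difference (anoxia under strong stratification),
  making DO anti-correlated with RWCS by construction.
* **Atmospheric pressure**: 92 kPa mean (site altitude) plus band-limited
  synoptic noise with periods of 2.5–8.5 d and 0.8 kPa standard deviation.
* **Currents/turbulence**: lognormal-modulated AR(1) near-bed currents,
  vertical-velocity RMS tied to them, dissipation higher under mixed
  conditions; daily chlorophyll-a higher after mixing periods, generated on
  its own daily grid (never downscaled).

Ebullition per site follows a latent sediment gas store
`S ← S + P(T)·Δ − R` with `P(T) = P₂₀·q₁₀^{(T−20)/10}` (defaults
P₂₀ = 40 mg CH₄ m⁻² d⁻¹, derived from incubation-scale production of the
emulated system's organic-rich top sediment layer, and q₁₀ = 4 — steeper
than a metabolic Q10 because unmodelled oxidation and diffusive losses in
cold, mixed periods are folded into the effective temperature response).
Storage capacity (4600 mg CH₄ m⁻², from acoustic gas-content estimates of
such sediments at ~12 m depth) always vents its overflow. Release otherwise
happens only while a trigger is active: the 6-h backward pressure-drop rate
exceeds its threshold or the near-bed current exceeds its threshold — the
synoptic-timescale pathways implicated in bubble release — with both
thresholds scaled by one calibrated multiplier so the fraction of
release-free days matches `zero_inflation_target` (default 0.5, the
zero-median behaviour of field daily fluxes). On each day with triggered
steps, a Beta-distributed fraction of the store is vented; the Beta mean
scales saturably with the day's integrated trigger excess (stronger forcing
vents more, at most twice the configured mean), amplified when absolute
pressure is low (bubbles expand and gain buoyancy); the day's total is then
allocated across that day's triggered steps with weights proportional to
trigger excess times Exp(1) draws. This puts the irreducible randomness at
sub-daily timescales while daily and weekly aggregates retain a genuine
driver-determined component — the structure that makes empirical models
timescale-dependent.

Inter-site synchrony is one knob: every random ingredient (trigger
perturbations, Beta fractions, allocation weights) mixes a shared and a
site-specific realization through a Gaussian copula with correlation
`synchrony_kappa`; κ = 1 gives bit-identical sites (Kuramoto r = 1), κ = 0
independent triggers. Marginal distributions do not change with κ.

`gen_abt_records` inverts the flux computation into a 30-s fill-height log
(in-situ volumes at the trap from surface temperature and
atmospheric + 2 m hydrostatic pressure, flushes at maximum fill height and
every 12 h, optional Gaussian height jitter). The valve convention is
lossless: gas arriving during a flush step stays in the tube, so the
round trip through the flux pipeline is exact to rounding.

**What the generator does not emulate.** No bubble mechanics, no spatial
sediment heterogeneity, no methane oxidation or diffusive flux, no
measurement gaps unless injected, and — most importantly — its event-level
stochasticity is larger than nature's: the additive model's absolute R²
on synthetic data (≈ 0.01/0.02/0.05–0.12/0.1–0.35 at 10 min/hourly/daily/
weekly) is far below the field study's values, although the qualitative
ordering weekly > daily > hourly > 10-min is reproduced robustly. Passing
tests therefore demonstrate the correctness and the timescale structure of
the methods, not field-level predictability.

## Problem sizes

Default study sizes were chosen so the whole suite runs comfortably on one
CPU: unit fixtures use three months at hourly cadence; synchrony sweeps use
four months × 10 seeds per coupling value; the timescale-ordering check uses
two years at 10-min cadence, averaged over three replicates (weekly fits
then rest on ~104 rows each, and averaging removes near-ties between two
small numbers).
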