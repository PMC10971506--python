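# Registry of empirical ebullition model forms from earlier studies of other
# aquatic systems, keyed by functional form and predictor set.
#
# Coefficients are deliberately set to "fit": the original publications'
# coefficient values are not shipped here, so every entry is refitted to the
# data set at hand before use.  To run a model with its original published
# coefficients, replace "fit" with the coefficient mapping its form expects
# (see ebullition.models.predict_literature_model).  Any numeric coefficients
# that appear in examples or tests of this package are synthetic
# placeholders, not transcriptions.
#
# Predictor-column naming convention (see ebullition.pipeline.assemble_table):
#   temp_bottom        sediment/bottom-water temperature (degC)
#   total_pressure     atmospheric + hydrostatic pressure (kPa)
#   d_total_pressure   backward first difference of total pressure per step
#   atm_pressure       atmospheric pressure (kPa)
#   d_atm_pressure     backward first difference of atmospheric pressure
#   wind_speed         wind speed (m s-1)
#   flux_lag1          methane flux at the previous time step
#   total_phosphorus   total phosphorus (ug L-1); not produced by the
#                      synthetic generator, supply externally
#   sediment_porosity, organic_matter_pct: site constants, supply externally

- name: binned_temp_polynomial
  form: binned_polynomial
  timescale: 1d
  predictors: [temp_bottom]
  coefficients: fit
  log_transform: false
  source: cubic polynomial of 1-degC-binned sediment temperature (postglacial lakes)

- name: pressure_temp_ann
  form: ann
  timescale: 1d
  predictors: [d_total_pressure, total_pressure, temp_bottom]
  coefficients: fit
  log_transform: false
  source: small neural network on pressure change, total pressure and bottom temperature

- name: biweekly_temp
  form: linear
  timescale: biweekly
  predictors: [temp_bottom]
  coefficients: fit
  log_transform: true
  source: log-linear sediment-temperature model for biweekly gas ebullition

- name: biweekly_temp_phosphorus
  form: linear
  timescale: biweekly
  predictors: [total_phosphorus, temp_bottom]
  coefficients: fit
  log_transform: true
  source: log-linear model with total phosphorus and sediment temperature

- name: arrhenius_binned_temp
  form: arrhenius
  timescale: 1d
  predictors: [temp_bottom]
  coefficients: fit
  log_transform: false
  source: modified Arrhenius law, flux at 20 degC times exp(theta * (T - 20))

- name: weekly_autoregressive
  form: autoregressive
  timescale: 1w
  predictors: [flux_lag1, temp_bottom, wind_speed, d_atm_pressure]
  coefficients: fit
  log_transform: false
  source: weekly autoregressive model with temperature, wind and pressure change

- name: sediment_properties
  form: linear
  timescale: 1d
  predictors: [temp_bottom, sediment_porosity, organic_matter_pct]
  coefficients: fit
  log_transform: false
  source: linear model with sediment temperature, porosity and organic matter content

- name: pressure_threshold
  form: pressure_threshold
  timescale: 1d
  predictors: [total_pressure]
  coefficients: fit
  log_transform: false
  source: release proportional to the drop of total pressure below a threshold
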