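# Small gridded experiment: 6-cell latitude gradient, 3 members, 10 years,
# baseline vs +2 degC warming. Run with:
#   maizegap run-all --config examples/config.yaml --out out/
seed: 7
start_year: 1985
n_years: 10
n_members: 3
cells:
  - [44.25, 8.25]
  - [46.25, 8.25]
  - [48.25, 8.25]
  - [50.25, 8.25]
  - [52.25, 8.25]
  - [54.25, 8.25]
ref_lat: 48.0
temp_lat_gradient: -0.6
climate:
  annual_mean_temp: 10.5
  seasonal_amplitude: 9.0
  wet_day_prob: 0.35
  wet_persistence: 0.6
  mean_wet_amount: 5.0
scenarios:
  baseline: {}
  warm2:
    delta_T: 2.0
    co2_start: 450.0
crop:
  gdd_maturity: 1122.0
  tbase: 8.0
  tupper: 30.0
sowing:
  window_start: [3, 1]
  window_end: [4, 29]
  tmin_threshold: 8.0
  persistence: 4
fertility_stress: 30.0
min_years: 5
unsuitable_below: 4.0
profitable_above: 7.0
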