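{
  "energy_label": "10FFF",
  "slope_m": 1.83e-4,
  "intercept_b": 0.9992,
  "slope_interval": [1.43e-4, 2.23e-4],
  "intercept_interval": [0.996, 1.003],
  "r_squared": 0.931,
  "fitted_support": [5.0, 110.0],
  "v_high": 300.0,
  "v_low": 150.0,
  "n_points": null,
  "seed": null
}
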