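{
  "energy_label": "6FFF",
  "slope_m": 9.67e-5,
  "intercept_b": 1.0010,
  "slope_interval": [6.54e-5, 1.28e-4],
  "intercept_interval": [0.999, 1.003],
  "r_squared": 0.706,
  "fitted_support": [5.0, 110.0],
  "v_high": 300.0,
  "v_low": 150.0,
  "n_points": null,
  "seed": null
}
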