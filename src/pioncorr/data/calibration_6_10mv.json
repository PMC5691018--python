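{
  "energy_label": "6/10MV",
  "slope_m": 5.15e-5,
  "intercept_b": 0.9999,
  "slope_interval": [-1.08e-4, 2.10e-4],
  "intercept_interval": [0.984, 1.016],
  "r_squared": 0.693,
  "fitted_support": [5.0, 110.0],
  "v_high": 300.0,
  "v_low": 150.0,
  "n_points": null,
  "seed": null
}
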