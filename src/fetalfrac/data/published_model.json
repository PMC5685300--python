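{
  "slope": 18.9,
  "intercept": -6.6,
  "r2": 0.99,
  "n_train": 23,
  "slope_se": null,
  "intercept_se": null
}
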