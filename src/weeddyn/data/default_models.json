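{
  "competition": {
    "intercept": 4.51,
    "sign": -1,
    "slope_magnitude": 0.02
  },
  "emergence_depth": {
    "intercept": 7.53,
    "slope": 1.36
  },
  "fecundity": {
    "c0": 5.85,
    "c1": -0.7,
    "c2": -0.14
  }
}
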