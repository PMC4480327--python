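{
  "allometric_slope": 1.0,
  "biomass_coeff": null,
  "crop_height": 80.0,
  "emergence_fraction": 0.071,
  "fertility": {
    "midpoint": 0.5,
    "seed_weight_slope": 0.1,
    "steepness": 2.0
  },
  "fresh_seed_loss": 0.79,
  "initial_seedbank": 1000.0,
  "seedbank_half_life": 1.0,
  "yield_loss_cap": 100.0
}
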