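{
  "interval_bounds": [
    0.0,
    1.0,
    2.0,
    3.0
  ],
  "baseline_hazard": [
    0.025,
    0.025,
    0.025
  ],
  "hazard_ratio": [
    0.4,
    0.4,
    0.4
  ],
  "exposure_rate": [
    0.0,
    0.0,
    0.0
  ],
  "initial_size": 1.0,
  "initial_unexposed_prop": 0.8,
  "steps_per_week": 1000
}
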