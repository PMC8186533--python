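# Null preset: both groups share identical latent-parameter distributions,
# so no feature should separate them beyond sampling noise. Values are the
# midpoints of the default preset's group means.
name: "null"
groups:
  ASD:
    base_speed: {mean: 460.0, sd: 55.0}
    speed_cv: {mean: 0.30, sd: 0.06}
    heading_noise_sd: {mean: 0.23, sd: 0.04}
    goal_gain: {mean: 0.38, sd: 0.06}
    fragmentation_rate: {mean: 0.95, sd: 0.25}
    accel_burst_sd: {mean: 335.0, sd: 65.0}
  TD:
    base_speed: {mean: 460.0, sd: 55.0}
    speed_cv: {mean: 0.30, sd: 0.06}
    heading_noise_sd: {mean: 0.23, sd: 0.04}
    goal_gain: {mean: 0.38, sd: 0.06}
    fragmentation_rate: {mean: 0.95, sd: 0.25}
    accel_burst_sd: {mean: 335.0, sd: 65.0}
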