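# Two-group preset with planted kinematic contrasts.
#
# ASD-like subjects drag with less goal attraction (lower straightness),
# more per-step heading jitter (more directional change), more finger lifts
# (shorter bouts), faster but more variable speed (high mean/max speed, low
# minimum speed) and larger acceleration bursts than TD-like subjects.
# Units: base_speed screen-units/s, heading_noise_sd radians,
# accel_burst_sd screen-units/s^2, fragmentation_rate lifts per drag.
name: default
groups:
  ASD:
    base_speed: {mean: 520.0, sd: 60.0}
    speed_cv: {mean: 0.45, sd: 0.08}
    heading_noise_sd: {mean: 0.38, sd: 0.06}
    goal_gain: {mean: 0.22, sd: 0.05}
    fragmentation_rate: {mean: 1.6, sd: 0.35}
    accel_burst_sd: {mean: 520.0, sd: 90.0}
  TD:
    base_speed: {mean: 400.0, sd: 50.0}
    speed_cv: {mean: 0.15, sd: 0.04}
    heading_noise_sd: {mean: 0.08, sd: 0.02}
    goal_gain: {mean: 0.55, sd: 0.08}
    fragmentation_rate: {mean: 0.30, sd: 0.12}
    accel_burst_sd: {mean: 150.0, sd: 40.0}
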