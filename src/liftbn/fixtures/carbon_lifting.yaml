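# Carbon-lifting scenario: a 50th-percentile female lifting carbon chunks
# (broken from smelter anodes, hence the wide hand-load distribution).
# Angles are link orientations in degrees from the horizontal; angle SDs are
# ergonomic posture-measurement errors converted from mean absolute errors
# under normality (the knee/ankle SD is the pooled across-joint value).
subject:
  stature_m: 1.618
  body_mass_kg: 65.6
posture:
  ankle: {mean_deg: 82.0, sd_deg: 9.4}
  knee: {mean_deg: 114.0, sd_deg: 9.4}
  torso: {mean_deg: 40.0, sd_deg: 6.3}
  shoulder: {mean_deg: 192.0, sd_deg: 7.9}
  elbow: {mean_deg: -56.0, sd_deg: 11.8}
hand_load:
  mean_kg: 53.1
  sd_kg: 12.8
erector_moment_arm_m: 0.053
strength:
  mean_n: 5448.0
  sd_n: 2366.0
simulation:
  n_iterations: 1000000
  seed: 2017
  vary: both
evidence: none
mode: deterministic
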