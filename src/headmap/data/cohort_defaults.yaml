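# Default calibration of the synthetic chronic-headache cohort generator.
# Targets: the published test-sample summaries (mean HIT-6 65.2, CH-QLQ
# RR/RP/EF means 50.3/63.4/48.8, mean EQ-5D utility 0.55, mean SF-6D 0.57,
# 82% female, mean age 48, range 18-88). Threshold values were calibrated
# by simulation at n = 20000 against those targets and then frozen.
demographics:
  female_proportion: 0.82
  age_mean: 48.0
  age_sd: 15.0
  age_min: 18
  age_max: 88
instruments:
  hit6: {mean: 65.2, loading: 5.5, noise: 2.5}
  chq_rr: {mean: 50.3, loading: -16.0, noise: 9.0}
  chq_rp: {mean: 63.4, loading: -17.0, noise: 10.0}
  chq_ef: {mean: 48.8, loading: -18.0, noise: 11.0}
eq5d:
  dim_loading: 0.8
  thresholds:
    MO: [0.87, 1.84]
    SC: [1.37, 2.14]
    UA: [0.07, 1.24]
    PD: [-1.33, 0.64]
    AD: [0.07, 1.14]
sf6d:
  dim_loading: 0.75
  thresholds:
    PF: [-0.59, 0.91]
    RL: [-1.49, -0.49, 0.61]
    SF: [-1.69, -0.89, 0.01, 1.01]
    PAIN: [-2.49, -1.49, -0.39, 0.71]
    MH: [-1.79, -0.89, 0.01, 1.01]
    VIT: [-2.09, -1.19, -0.19, 0.91]
age_effect: 0.0
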