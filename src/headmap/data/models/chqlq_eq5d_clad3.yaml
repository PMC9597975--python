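# CH-QLQ -> EQ-5D (5L cross-walked to UK 3L tariff), CLAD, covariate set 3.
# Term order follows the published coefficient table verbatim; values that
# print as 0.0000 / -0.0000 are stored as zero (printed precision).
name: chqlq_eq5d_clad3
estimator: clad
source: chqlq
target: eq5d
covariate_set: 3
censor_upper: 1.0
terms:
  - [chqrr, 0.0107]
  - [chqrp, 0.0127]
  - [chqef, 0.0007]
  - [chqrr_sq, -0.0000]
  - [chqrp_sq, -0.0001]
  - [chqef_sq, 0.0000]
  - [chqrr_x_chqrp, -0.0000]
  - [chqrr_x_chqef, -0.0002]
  - [chqrp_x_chqef, 0.0001]
  - [chqrr_x_age, 0.0000]
  - [chqrp_x_age, 0.0001]
  - [chqef_x_age, -0.0000]
  - [age, 0.0013]
  - [age_sq, -0.0001]
  - [female, 0.0326]
constant: -0.3964
provenance: "published mapping coefficients, chronic-headache test sample (n=349)"
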