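# HIT-6 -> EQ-5D (5L cross-walked to UK 3L tariff), CLAD, covariate set 1.
# Coefficients stored exactly as published (4 decimals).
name: hit6_eq5d_clad1
estimator: clad
source: hit6
target: eq5d
covariate_set: 1
censor_upper: 1.0
terms:
  - [hit6, -0.0198]
constant: 1.9054
provenance: "published mapping coefficients, chronic-headache test sample (n=349)"
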