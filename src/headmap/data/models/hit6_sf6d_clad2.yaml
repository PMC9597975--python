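# HIT-6 -> SF-6D (from SF-12), CLAD, covariate set 2.
name: hit6_sf6d_clad2
estimator: clad
source: hit6
target: sf6d
covariate_set: 2
censor_upper: 1.0
terms:
  - [hit6, -0.0118]
  - [age, -0.0002]
  - [female, -0.0142]
constant: 1.3669
provenance: "published mapping coefficients, chronic-headache test sample (n=349)"
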