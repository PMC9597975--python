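# CH-QLQ -> SF-6D (from SF-12), OLS, covariate set 2.
name: chqlq_sf6d_ols2
estimator: ols
source: chqlq
target: sf6d
covariate_set: 2
terms:
  - [chqrr, 0.0018]
  - [chqrp, 0.0017]
  - [chqef, 0.0009]
  - [age, -0.0002]
  - [female, -0.0032]
constant: 0.3459
provenance: "published mapping coefficients, chronic-headache test sample (n=349)"
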