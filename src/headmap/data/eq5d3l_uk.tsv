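# EQ-5D-3L UK TTO value set (Dolan 1997 "MVH A1" model).
# Additive: utility = constant - sum(dimension decrements) - extra-term decrements.
# Dimensions ordered (MO, SC, UA, PD, AD); levels 1-based; level-1 decrement is 0.
# provenance: UK general-population time-trade-off tariff, standard published coefficients.
constant	1.0
extra	any_beyond_level1	0.081
extra	any_at_worst	0.269
decrement	MO	2	0.069
decrement	MO	3	0.314
decrement	SC	2	0.104
decrement	SC	3	0.214
decrement	UA	2	0.036
decrement	UA	3	0.094
decrement	PD	2	0.123
decrement	PD	3	0.386
decrement	AD	2	0.071
decrement	AD	3	0.236
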