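# SYNTHETIC SF-6D (SF-12 variant) tariff fixture.
# This is NOT the published Brazier/Roberts coefficient table: it is a stand-in
# with the published structure (six dimensions PF/RL/SF/PAIN/MH/VIT with
# 3/4/5/5/5/5 levels, a worst-level "MOST" extra term) calibrated so that the
# floor equals the published SF-12 SF-6D floor of 0.345 and utility is weakly
# decreasing in every dimension level. Replace with the licensed table for
# applied work.
# provenance: synthetic; scoring-variant unknown upstream, see package docs.
constant	1.0
extra	any_at_worst	0.070
decrement	PF	2	0.050
decrement	PF	3	0.090
decrement	RL	2	0.050
decrement	RL	3	0.055
decrement	RL	4	0.060
decrement	SF	2	0.055
decrement	SF	3	0.060
decrement	SF	4	0.080
decrement	SF	5	0.100
decrement	PAIN	2	0.040
decrement	PAIN	3	0.070
decrement	PAIN	4	0.100
decrement	PAIN	5	0.140
decrement	MH	2	0.050
decrement	MH	3	0.060
decrement	MH	4	0.095
decrement	MH	5	0.125
decrement	VIT	2	0.045
decrement	VIT	3	0.050
decrement	VIT	4	0.060
decrement	VIT	5	0.070
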