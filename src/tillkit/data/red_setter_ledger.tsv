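dose	seeds_treated	m1_transplanted	m2_families	m3_families
0.7% EMS	11,000	8,500	4,741	4,156
1% EMS	12,000	4,500	1,926	1,352
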