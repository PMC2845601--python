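gene	amplicon_kb	families_screened	mutations	dose
Rab11a	0.407	1,373	1	0.7% EMS
PG	2.587	2,791	7	0.7% EMS
Exp1	1.025	3,885	14	0.7% EMS
RIN	1.331	3,885	4	0.7% EMS
Gr	1.409	3,885	5	0.7% EMS
Lcy-b	1.274	3,801	4	0.7% EMS
Lcy-e	1.414	3,630	6	0.7% EMS
Rab11a	0.407	713	3	1% EMS
PG	2.587	963	2	1% EMS
Exp1	1.025	1,284	6	1% EMS
RIN	1.331	1,284	8	1% EMS
Gr	1.409	1,284	3	1% EMS
Lcy-b	1.274	1,252	3	1% EMS
Lcy-e	1.414	1,185	0	1% EMS
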