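type_number	name	n_proteins
1	Amniotic fluid	192
2	Bronchoalveolar lavage fluid	65
3	Cerebrospinal fluid	204
4	Milk	71
5	Nipple aspiration fluid	37
6	Plasma/Serum	418
7	Saliva	175
8	Seminal fluid	155
9	Synovial fluid	63
10	Tear	84
11	Urine	244
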