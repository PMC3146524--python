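type_number	name
1	Amniotic fluid
2	Bronchoalveolar lavage fluid
3	Cerebrospinal fluid
4	Milk
5	Nipple aspiration fluid
6	Plasma/Serum
7	Saliva
8	Seminal fluid
9	Synovial fluid
10	Tear
11	Urine
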