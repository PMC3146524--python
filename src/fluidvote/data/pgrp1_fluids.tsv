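protein	fluids
O75594	6,7,11
P61626	1,2,3,4,6,7,8,10,11
O15263	7
P05231	6
P13500	6
P60022	6,11,7
P01350	6
P78380	11
P07492	8
P02743	3,6,7,8,9,10,11
P05120	6,7,10
P35858	1,3,6,9,11
P49913	1,6,7,8,11
P01375	6
Q13410	4,5
P48023	6
P19883	6
P05814	3,4,5
P11226	6
Q14116	6
P13236	6
P02788	1,3,5,6,7,8,10,11
P13501	6
P13591	3,6,11
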