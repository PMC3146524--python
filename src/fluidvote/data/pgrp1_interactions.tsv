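protein_a	protein_b	confidence
O75594	P61626	0.532
O75594	O15263	0.501
O75594	P05231	0.300
O75594	P13500	0.291
O75594	P60022	0.291
O75594	P01350	0.286
O75594	P78380	0.279
O75594	P07492	0.257
O75594	P02743	0.249
O75594	P05120	0.243
O75594	P35858	0.235
O75594	P49913	0.232
O75594	P01375	0.227
O75594	Q13410	0.221
O75594	P48023	0.218
O75594	P19883	0.207
O75594	P05814	0.196
O75594	P11226	0.191
O75594	Q14116	0.162
O75594	P13236	0.156
O75594	P02788	0.154
O75594	P13501	0.154
O75594	P13591	0.154
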