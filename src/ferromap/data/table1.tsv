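sample	c_mg_ml	cfe_ug_ml	mean	sd	n	se
0	0	0	140.1	87.5	1303	2.423
1	0.02	9.6	228.0	53.7	920	1.769
2	0.04	19.2	279.3	65.2	2399	1.332
3	0.06	28.8	287.5	58.8	4677	0.860
4	0.08	38.4	492.7	63.3	2153	1.364
5	0.10	48	506.1	77.1	2271	1.618
6	0.12	57.6	655.7	101.2	2245	2.136
7	0.14	67.2	731.0	92.0	2128	1.995
8	0.16	76.8	846.1	161.9	2110	3.525
9	0.18	86.4	1018.3	157.8	2073	3.465
10	0.20	96	1074.0	140.5	2117	3.053
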