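20	24	0	24
14	15	18	8
29	1	8	11
17	12	3	1
0	1	4	29
5	19	22	7
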