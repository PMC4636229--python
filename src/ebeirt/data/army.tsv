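A	B	C	D	count
0	0	0	0	229
0	0	0	1	199
0	0	1	0	52
0	0	1	1	96
0	1	0	0	25
0	1	0	1	60
0	1	1	0	16
0	1	1	1	69
1	0	0	0	16
1	0	0	1	45
1	0	1	0	8
1	0	1	1	55
1	1	0	0	10
1	1	0	1	42
1	1	1	0	3
1	1	1	1	75
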