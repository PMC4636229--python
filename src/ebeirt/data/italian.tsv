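item1	item2	item3	item4	count	group
0	0	0	0	342	African
0	0	0	1	164	African
0	0	1	0	35	African
0	0	1	1	44	African
0	1	0	0	53	African
0	1	0	1	60	African
0	1	1	0	18	African
0	1	1	1	51	African
1	0	0	0	35	African
1	0	0	1	39	African
1	0	1	0	9	African
1	0	1	1	28	African
1	1	0	0	11	African
1	1	0	1	39	African
1	1	1	0	13	African
1	1	1	1	66	African
0	0	0	0	361	EastEuropean
0	0	0	1	129	EastEuropean
0	0	1	0	32	EastEuropean
0	0	1	1	47	EastEuropean
0	1	0	0	41	EastEuropean
0	1	0	1	51	EastEuropean
0	1	1	0	20	EastEuropean
0	1	1	1	38	EastEuropean
1	0	0	0	45	EastEuropean
1	0	0	1	47	EastEuropean
1	0	1	0	20	EastEuropean
1	0	1	1	27	EastEuropean
1	1	0	0	10	EastEuropean
1	1	0	1	36	EastEuropean
1	1	1	0	17	EastEuropean
1	1	1	1	73	EastEuropean
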