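health	sick	count
1	1	9
1	2	3
1	3	7
1	4	1
2	1	4
2	2	3
2	3	7
2	4	6
3	1	15
3	2	19
3	3	65
3	4	51
4	1	15
4	2	14
4	3	80
4	4	248
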