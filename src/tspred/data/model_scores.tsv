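template	seq_id_pct	dope	ga341
1pqj:A	90.8	-2.08	1.00
1d3n:A	86.1	-1.96	1.00
1t8a:A	81.6	-1.65	1.00
1cx6:A	79.9	-2.03	1.00
1lpy:A	78.8	-1.95	1.00
1swz:A	77.5	-2.21	1.00
1lwk:A	77.0	-1.74	1.00
1swy:A	74.5	-2.22	1.00
1sx2:A	72.4	-2.28	1.00
1wth:A	43.2	-1.49	1.00
1k28:A	43.2	-1.43	1.00
2anv:A	24.2	0.54	0.12
2anx:B	23.9	0.60	0.08
2anv:B	23.5	0.49	0.13
2anx:A	22.1	0.64	0.13
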