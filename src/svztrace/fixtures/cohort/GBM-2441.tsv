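chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	31	1000	251	1000	239
chrX	77597580	C	A	ATRX	1000	0	1000	0	1000	185	1000	0
chr7	55198717	G	A	EGFR	1000	0	1000	0	1000	0	1000	175
chr17	7673803	G	A	TP53	1000	0	1000	0	1000	0	1000	160
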