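chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	28	1000	255	1000	240
chr3	179218303	G	A	PIK3CA	1000	0	1000	0	1000	220	1000	205
chr17	7675088	C	T	TP53	1000	0	1000	0	1000	170	1000	0
chrX	77683000	G	A	ATRX	1000	0	1000	0	1000	0	1000	130
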