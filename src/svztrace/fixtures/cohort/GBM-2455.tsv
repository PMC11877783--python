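chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	27	1000	244	1000	241
chr7	55174771	G	A	EGFR	1000	0	1000	0	1000	200	30	0
chr17	7670699	C	T	TP53	1000	0	1000	0	30	1	1000	190
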