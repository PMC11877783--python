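chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	26	1000	250	1000	246
chr7	55191822	T	G	EGFR	1000	0	1000	23	1000	240	1000	238
chr17	31258000	A	G	NF1	1000	0	1000	0	1000	180	1000	0
chr17	7676154	C	T	TP53	1000	0	1000	0	1000	170	1000	0
chrX	77643500	G	A	ATRX	1000	0	1000	0	1000	0	1000	165
chr3	179234297	A	G	PIK3CA	1000	0	1000	0	1000	0	1000	158
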