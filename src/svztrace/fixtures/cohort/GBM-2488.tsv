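chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	26	1000	246	1000	244
chr10	87961042	AACTT	A	PTEN	1000	0	1000	0	1000	205	1000	0
chr10	87864488	TCTTGAT	T	PTEN	1000	0	1000	0	1000	0	1000	195
chr7	55191822	T	G	EGFR	1000	0	1000	0	1000	165	1000	0
chr17	31350290	C	T	NF1	1000	0	1000	0	1000	0	1000	155
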