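chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	30	1000	250	1000	245
chr7	55181378	C	T	EGFR	1000	0	1000	0	1000	210	1000	190
chr17	31226000	G	A	NF1	1000	0	1000	0	1000	160	1000	0
chr13	48381415	C	T	RB1	1000	0	1000	0	1000	0	1000	150
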