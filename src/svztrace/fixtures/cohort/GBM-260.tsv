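chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	24	1000	249	1000	243
chr4	54285926	C	T	PDGFRA	1000	0	1000	0	1000	150	1000	0
chr13	48367512	G	T	RB1	1000	0	1000	0	1000	145	1000	0
chr10	87952220	C	T	PTEN	1000	0	1000	0	1000	0	1000	140
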