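chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	25	1000	247	1000	237
chr4	54229500	G	T	PDGFRA	1000	0	1000	0	1000	150	25	0
chr13	48303900	C	A	RB1	1000	0	1000	0	28	0	1000	140
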