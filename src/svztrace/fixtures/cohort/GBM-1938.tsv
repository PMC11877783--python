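chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	29	1000	252	1000	247
chr4	54274888	C	T	PDGFRA	1000	0	1000	25	1000	230	1000	225
chr10	87894050	G	A	PTEN	1000	0	1000	28	1000	235	1000	240
chr17	7674872	T	C	TP53	1000	0	1000	0	1000	190	1000	0
chr17	7674961	G	A	TP53	1000	0	1000	0	1000	0	1000	185
chr3	179239627	A	T	PIK3CA	1000	0	1000	0	1000	175	1000	0
chr3	179203765	G	A	PIK3CA	1000	0	1000	0	1000	0	1000	180
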