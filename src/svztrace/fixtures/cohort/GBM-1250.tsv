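chrom	pos	ref	alt	gene	blood_depth	blood_alt	svz_depth	svz_alt	primary_depth	primary_alt	recurrent_depth	recurrent_alt
chr5	1295228	G	A	TERT	1000	0	1000	27	1000	248	1000	242
chr10	87957915	A	T	PTEN	1000	0	1000	0	1000	240	1000	0
chr10	87933010	C	G	PTEN	1000	0	1000	0	1000	0	1000	230
chr1	158666421	A	C	SPTA1	1000	0	1000	0	1000	210	1000	0
chr1	158680532	C	T	SPTA1	1000	0	1000	0	1000	0	1000	200
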