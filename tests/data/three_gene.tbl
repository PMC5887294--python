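>Feature scaffold1
564	62	gene
			gene	cytB
			locus_tag	TEST_000001
564	328	mRNA
238	62
			product	cytochrome b
564	328	CDS
238	62
			product	cytochrome b
724	1375	gene
			locus_tag	TEST_000002
724	977	mRNA
1008	1104
1169	1375
<724	977	CDS
1008	1104
1169	1375
			db_xref	PFAM:PF00069
2059	1436	gene
			locus_tag	TEST_000003
2059	1812	mRNA
1691	1436
2059	1812	CDS
1691	>1436
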