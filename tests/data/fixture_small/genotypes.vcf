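##fileformat=VCFv4.2
##source=divabc 0.1.0
##contig=<ID=locus_0000,length=200>
##contig=<ID=locus_0001,length=200>
##contig=<ID=locus_0002,length=200>
##contig=<ID=locus_0003,length=200>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	coll_01	coll_02	coll_03	coll_04	pied_01	pied_02	pied_03	pied_04
locus_0000	129	.	A	T	.	PASS	.	GT	0/0	0/0	0/0	0/0	./.	1/1	1/1	./.
locus_0000	173	.	A	T	.	PASS	.	GT	0/0	1/0	1/0	0/1	0/0	0/0	0/0	0/0
locus_0001	59	.	A	T	.	PASS	.	GT	./.	0/0	0/0	0/0	1/1	1/1	./.	./.
locus_0001	79	.	A	T	.	PASS	.	GT	0/0	0/0	0/1	./.	0/0	./.	0/0	0/0
locus_0001	113	.	A	T	.	PASS	.	GT	0/0	0/0	0/0	0/0	1/1	1/1	1/1	./.
locus_0003	13	.	A	T	.	PASS	.	GT	1/1	1/1	1/1	1/1	0/0	0/0	0/0	0/0
locus_0003	22	.	A	T	.	PASS	.	GT	0/0	0/0	./.	0/0	0/1	1/1	0/1	0/1
locus_0003	34	.	A	T	.	PASS	.	GT	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0
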