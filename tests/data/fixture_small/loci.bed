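locus_0000	0	200	locus_0000
locus_0001	0	200	locus_0001
locus_0002	0	200	locus_0002
locus_0003	0	200	locus_0003
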