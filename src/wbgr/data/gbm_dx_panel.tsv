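gene_id	rna_class	expected_direction
MMP9	mRNA	up
TMEM92	mRNA	up
C1orf226	mRNA	up
CD163	mRNA	up
LINC00482	lncRNA	up
miR-3918	miRNA	up
AK5	mRNA	down
CD200	mRNA	down
MICU3	mRNA	down
miR-760	miRNA	down
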