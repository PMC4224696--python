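# Published annotations of the two recurrent TERT promoter mutations
# (chr5:1,295,228 G>A and chr5:1,295,250 G>A), as produced by the
# cell-type-aware annotation of neural progenitor cells. TERT is on the
# minus strand; distances are signed in the gene's orientation.
chrom	pos	ref	alt	sample	gene	distance_to_tss	dhs	h3k4me1	h3k4me3	h3k27ac	conservation	created	removed	fantom_promoter	fantom_enhancer
chr5	1295228	G	A	TERT_mut1	TERT	-66	1	0	1	0	0.008	ELK1;ELF1;FLI1;ELK4;GABPA	TFAP2A	1	0
chr5	1295250	G	A	TERT_mut2	TERT	-88	1	0	1	0	0	ELK1;ELF1;FLI1;ELK4;GABPA		1	0
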