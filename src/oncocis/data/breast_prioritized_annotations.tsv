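# Published prioritized cis-regulatory mutation annotations from 17
# whole-genome-sequenced breast cancers (HMEC chromatin context), sorted
# by differential-expression p-value. Every record satisfies: in a DHS,
# flanking H3K4me1 or H3K4me3, mammalian conservation > 0.8, and >= 1
# transcription-factor motif created or removed, with adjusted p < 0.05.
# ref/alt alleles are not part of the published record except for the
# experimentally followed-up CDK6 mutation (chr7:92,347,495 G>C).
chrom	pos	ref	alt	sample	gene	distance_to_tss	fold_change	adj_p_value	dhs	h3k4me1	h3k4me3	h3k27ac	conservation	created	removed	fantom_promoter	fantom_enhancer	regulomedb	funseq_sensitive
chr6	71108774			PD4006a	COL9A1	-95988	100.12	1.39E-23	1	1	1	1	1	Hand1::Tcfe2a	Klf1	1	0	4	No
chr1	160094923			PD4116a	ATP1A2	-9404	71.15	2.99E-19	1	1	0	1	0.981	ELF1;Hltf	SP1;ZEB1	1	0	4	No
chr7	92347495	G	C	PD4107a	CDK6	118446	5.06	7.75E-07	1	1	1	1	1		NFIC;THAP1	1	0	4	No
chr9	109651512			PD4006a	ZNF462	-26135	4.79	2.27E-06	1	1	0	1	0.993		EHF;Erg;FLI1;PPARG::RXRA	0	0	5	No
chr1	208412585			PD4116a	PLXNA2	5080	1.63	4.17E-06	1	1	0	1	0.993	Nobox;Hltf		0	1	4	No
chr4	75560994			PD4103a	BTC	158888	2.38	7.39E-05	1	1	0	0	0.938		CREB1;Mafb	0	0	4	No
chr5	97643723			PD4109a	RGMB	461275	2.50	2.47E-04	1	1	0	1	0.801		ARID3A	0	1	3a	No
chr17	2080270			PD4005a	HIC1	-120667	1.29	4.02E-04	1	1	0	1	1	NFIC		0	0	5	No
chr16	57334425			PD4115a	PLLP	-15841	2.09	8.51E-04	1	1	1	1	1		TFAP2C	1	0	4	Yes
chr2	219147431			PD4198a	TMBIM1	9849	1.65	2.23E-03	1	1	0	1	0.973	Foxd3	NFATC2;Erg	1	0	5	No
chr8	100811550			PD4116a	COX6C	94692	2.46	2.63E-03	1	1	0	0	1		NFKB1;Stat4;Spi1;Bcl6	0	0	2b	No
chr14	37612228			PD4115a	SLC25A21	29637	1.54	3.15E-03	1	1	0	0	1	Hand1::Tcfe2a	RUNX1;RUNX2;FOXI1	0	0	2b	No
chr1	185688035			PD4005a	HMCN1	15647	0.61	4.98E-03	1	1	0	1	0.997	FOXP1;FOXL1		0	0	5	No
chr2	208890286			PD3904a	PLEKHM3	-2	1.48	1.09E-02	1	1	1	1	0.998		ELF5;GABPA;FLI1;ELK4;ELK1	1	0	2b	No
chr10	93058182			PD4005a	PCGF5	-77814	0.65	2.28E-02	1	1	0	0	0.935		Zfx	1	0	2a	No
chr7	22617382			PD4107a	IL6	-149383	2.29	2.62E-02	1	1	0	1	1	Hltf;CEBPA;CEBPB	AR	1	1	2a	Yes
chr6	26533145			PD4192a	HMGN4	5426	0.49	2.62E-02	1	1	0	0	0.979		Zfx	0	1	2b	Yes
chr22	31644327			PD4103a	LIMK2	-36078	0.79	3.43E-02	1	1	1	1	0.989		Klf4;SP2;SP1;KLF5;Klf1;ELK1	1	0	3a	No
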