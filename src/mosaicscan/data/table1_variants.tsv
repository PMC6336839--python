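variant	sample_id	diagnosis	cell_type	pop_af	depth	vaf_percent	functional_class	gene	cadd_raw	cadd_phred
9:130263483|C>T	C1	control	non_neuronal	0	313	2.88	intronic	LRSAM1	0.18	4.52
12:120582181|G>T	C5	control	non_neuronal	0	188	3.72	exonic_lof	GCN1	6.47	30.00
17:2575935|G>T	C5	control	neuronal	0	80	6.25	intronic	PAFAH1B1	-0.11	1.68
5:133747485|C>T	C6	control	neuronal	1.48E-05	187	3.74	exonic_nonsynonymous	CDKN2AIPNL	2.41	18.91
X:25014005|C>T	C6	control	neuronal	0	660	2.27	exonic_lof	POLA1	12.14	38.00
15:42439899|C>T	C10	control	neuronal	0	182	3.85	exonic_nonsynonymous	PLA2G4F	6.59	31.00
9:2718448|C>T	C10	control	non_neuronal	0	214	3.74	exonic_nonsynonymous	KCNV2	5.59	26.50
15:45695252|G>A	S1	case	neuronal	0	117	4.27	exonic_nonsynonymous	SPATA5L1	1.00	10.65
8:6338368|C>T	S1	case	non_neuronal	7.45E-05	132	3.79	exonic_nonsynonymous	MCPH1	6.53	31.00
1:43850087|C>T	S3	case	non_neuronal	5.82E-05	413	3.87	utr3	MED8	0.16	4.25
11:120838140|C>T	S3	case	non_neuronal	0	173	3.47	intronic	GRIK4	-0.01	2.52
4:52779777|C>T	S3	case	non_neuronal	0	243	3.29	utr3	DCUN1D4	0.94	10.32
X:120183145|C>G	S3	case	non_neuronal	0	398	2.76	exonic_nonsynonymous	GLUD2	3.92	23.50
X:75650577|C>G	S3	case	non_neuronal	0	403	2.73	exonic_nonsynonymous	MAGEE1	3.22	22.70
X:77298037|G>A	S3	case	non_neuronal	0	117	4.27	intronic	ATP7A	-0.13	1.52
9:133267386|G>A	S4	case	neuronal	0	196	4.59	exonic_synonymous	HMCN2	0.64	8.41
1:228540840|C>T	S7	case	non_neuronal	0	242	3.72	intronic	OBSCN	0.50	7.44
19:58187980|G>A	S7	case	non_neuronal	0	183	7.10	intronic	ZSCAN4	0.12	3.87
22:41527619|C>T	S7	case	non_neuronal	0	146	4.79	exonic_nonsynonymous	EP300	5.93	27.60
4:163032431|G>A	S7	case	neuronal	1.65E-05	204	4.41	exonic_lof	FSTL5	10.65	36.00
11:89155084|C>T	S8	case	non_neuronal	4.99E-05	180	6.11	exonic_synonymous	NOX4	2.29	18.11
11:89155084|C>T	S8	case	neuronal	4.99E-05	102	4.90	exonic_synonymous	NOX4	2.29	18.11
12:49360144|G>A	S8	case	non_neuronal	1.83E-04	343	4.96	exonic_nonsynonymous	WNT10B	7.27	34.00
12:49360144|G>A	S8	case	neuronal	1.83E-04	409	2.93	exonic_nonsynonymous	WNT10B	7.27	34.00
22:32198753|C>T	S8	case	non_neuronal	0	263	3.04	exonic_nonsynonymous	DEPDC5	7.10	34.00
5:177688699|G>A	S8	case	non_neuronal	0	271	2.95	intronic	COL23A1	0.17	4.41
16:72166900|G>A	S9	case	neuronal	0	159	3.77	intronic	PMFBP1	1.08	11.11
16:90015951|G>A	S9	case	neuronal	0	162	3.70	exonic_synonymous	DEF8	0.35	6.14
17:78182086|G>A	S9	case	neuronal	7.27E-05	273	2.93	exonic_nonsynonymous	CARD14	2.84	21.60
19:7566139|G>T	S9	case	neuronal	0	145	3.45	exonic_nonsynonymous	C19orf45	1.00	10.66
22:42373091|G>A	S9	case	non_neuronal	0	108	5.56	intronic	SEPT3	1.74	14.63
8:30705911|G>T	S9	case	non_neuronal	0	431	2.78	exonic_nonsynonymous	TEX15	3.62	23.20
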