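gene_set	p_value	fdr	success_rate_percent	set_size	overlap_case	overlap_control	odds_ratio	case_genes
Prenatal brain expression	0.026	0.096	100	1427	3	0	6.723	PMFBP1;OBSCN;ATP7A
De novo in schizophrenia	0.026	0.096	100	854	4	0	8.627	PMFBP1;TEX15;EP300;OBSCN
FMRP targets	0.060	0.096	0	776	2	0	4.818	EP300;SEPT3
PGC2-GWAS	0.060	0.096	0	333	2	0	4.818	EP300;SEPT3
Postnatal brain expression	0.060	0.096	0	1396	2	0	4.818	COL23A1;GRIK4
De novo in control	0.145	0.166	NA	528	1	0	2.913	EP300
Neuronal proteome:PSD	0.145	0.166	NA	659	1	0	2.913	SEPT3
PGC2-CNV	1	1	NA	160	0	0	1.008	NA
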