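ID	Gender	Age	Morphology	Gene	Chr	Location	SNP IDS	REF	VAR	Variant Type	Protein Change	Variant Impact	METASVM	METALR	CADD	HGMD/ClinVar	gnomAD Exomes EAS	gnomAD Genomes EAS	Pathway/Process
1804	M	65	Conventional	ATP8B2	1	154317567		A	C	missense	Lys836Gln	moderate	D	D	26.2		1.74e-04	0	Mesoderm commitment
1686	M	64	Conventional	LRP2	2	170033035		C	T	missense	Gly3486Glu	moderate	D	D	33		0	0	Sonic Hedgehog
1372	NA	NA	NA	LRP2	2	170062924	rs577943281	T	A	missense	Thr2436Ser	moderate	D	D	22.7		2.90e-04	6.17e-04	Sonic Hedgehog
1964	M	24	Chondroid	LRP2	2	170055366	rs755215116	A	C	missense	Ile2836Met	moderate	D	D	24.2		3.66e-03	6.17e-04	Sonic Hedgehog
1442	NA	NA	NA	PDK1	2	173460575	rs745678398	A	G	structural interaction		High					0	0	PI3K/AKT/mTOR
1886	F	62	Conventional	TCF7L1	2	85536476		C	T	missense	Thr553Ile	moderate	D	D	23		5.82e-05	0	Mesoderm commitment
1790	M	65	Conventional	TCF7L1	2	85531113	rs373770977	G	A	missense	Val252Ile	moderate	D	D	23.4		1.25e-04	0	Mesoderm commitment
1779	M	47	Conventional	TCF7L1	2	85536536	rs555810312	C	T	missense	Pro573Leu	moderate	D	D	23.2		4.19e-04	0	Mesoderm commitment
2011	F	7	Conventional	TBXT	6	166581010	rs563349798	C	G	missense	Val24Leu	moderate	D	D	29.7		0	0	T super-enhancer
1686	M	64	Conventional	EXT1	8	118819501	rs753261171	G	A	missense	Thr613Met	moderate	D	D	33		0	0	Mesoderm commitment
776	M	54	Conventional	SUFU	10	104309738		C	T	structural interaction		High					5.80e-05	0	Sonic Hedgehog
1921	M	57	Conventional	EXT2	11	44193231	rs767085143	A	G	missense	Asn448Ser	moderate	D	D	24.3		2.90e-04	0	Mesoderm commitment
1372	NA	NA	NA	COL2A1	12	48369322	rs995646562	C	T	missense	Ala1222Thr	moderate	D	D	24.1		0	0	Notochord development
1909	M	26	Conventional	COL2A1	12	48372528		G	T	missense	Pro916His	moderate	D	D	25		0	0	Notochord development
1936	F	71	Conventional	TSC2	16	2134572	rs45517338	C	G	missense	Pro1450Arg	moderate	D	D	25.8		2.35e-04	0	PI3K/AKT/mTOR
1417	M	59	Conventional	TSC2	16	2134572	rs45517338	C	G	missense	Pro1450Arg	moderate	D	D	25.8		2.35e-04	0	PI3K/AKT/mTOR
1979	M	59	Chondroid	TSC2	16	2121610	rs45509392	G	A	missense	Asp647Asn	moderate	D	D	32	DM	5.80e-04	0	PI3K/AKT/mTOR
1570	M	24	Chondroid	TSC2	16	2121610	rs45509392	G	A	missense	Asp647Asn	moderate	D	D	32	DM	5.80e-04	0	PI3K/AKT/mTOR
462	F	62	Conventional	TSC2	16	2121610	rs45509392	G	A	missense	Asp647Asn	moderate	D	D	32	DM	5.80e-04	0	PI3K/AKT/mTOR
1084	NA	NA	NA	ACACA	17	35549102	rs772483773	C	T	missense	Val1449Met	moderate	D	D	25.2		6.96e-04	6.17e-04	Mesoderm commitment
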