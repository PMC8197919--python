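ID	Gender	Age	Morphology	Site	Gene	Chr	Location	SNP IDS	REF	VAR	Variant Type	Protein Change	Variant Impact	METASVM	METALR	CADD	HGMD/ClinVar	gnomAD Exomes NFE	gnomAD Genomes NFE	Pathway/Process
1004	Female	NA	Conventional	1	ATP8B2	1	154305114		G	T	missense	Arg210Leu	moderate	D	D	34		1.06e-05		Mesoderm commitment
1101	Male	37.2	Conventional	2	LYST	1	235922291		G	A	stop_gained	Arg2288*	high							Driver
1164	Male	29.7	Conventional	1	TCF7L1	2	85529694	rs147750102	G	A	missense	Gly205Ser	moderate	D	D	22.4		9.67e-05	6.49e-05	Mesoderm commitment
1040	Female	32.7	Conventional	1	EPB41L5	2	120776677	rs200315720	G	A	missense	Arg6His	moderate	D	D	29.9		1.98e-04	1.30e-04	Mesoderm commitment
1020	Female	39.0	Conventional	1	EPB41L5	2	120833086	rs766560121	C	A	missense	Leu148Ile	moderate	D	D	28.9		0		Mesoderm commitment
3001	NA	NA	NA	NA	LRP2	2	170038097	rs137983840	C	T	missense	Ala3344Thr	moderate	D	D	26.3		6.16e-05	6.48e-05	Sonic Hedgehog
1035	Female	26.1	Chondroid	1	PDK1	2	173460594			T	frameshift & stop_gained	Asn424fs	high							PI3K/AKT/mTOR
1111	Male	51.3	Chondroid	1	NFE2L2	2	178095743		C	A	missense	Asp530Tyr	moderate	D	D	22.5				Mesoderm commitment
1014	Female	44.3	Conventional	1	BMPR2	2	203420750	rs146310981	G	A	missense	Val788Ile	moderate	D	D	22.7		3.52e-05		Mesoderm commitment
1139	Female	39.5	Conventional	1	RARB	3	25611341		A	G	missense	Thr188Ala	moderate	D	D	22.9		8.79e-06		Mesoderm commitment
1053	Female	54.6	Conventional	1	HHIP	4	145581068			ACAC	frameshift	Phe304fs	high					0		Sonic Hedgehog
1127	Male	50.7	Conventional	3	SRF	6	43146888	rs765592889	T	C	missense	Val496Ala	moderate	D	D	22.4		1.76e-05		Mesoderm commitment
1048/5320	NA	NA	NA	NA	TBXT	6	166571981	rs368179445	C	T	missense	Arg377Gln	moderate	D	D	25.5		0		T super-enhancer
1080	Female	47.4	Conventional	1	ATP6V1B2	8	20068082		C	T	missense & splice region	Arg130Trp	moderate	D	D	35		0		T super-enhancer
1161	Male	78.3	Conventional	1	EXT1	8	118832021	rs145720047	G	C	missense	Pro477Arg	moderate	D	D	22.4		1.24e-04	6.48e-05	Mesoderm commitment
1001	Female	47.0	Conventional	1	DEPTOR	8	120977595			A	frameshift	Glu185fs	high							PI3K/AKT/mTOR
1034	Female	51.0	Conventional	2	SMARCA2	9	2039568	rs774084308	C	T	missense	Pro153Leu	moderate	D	D	22.2		0		SWI/SNF complex
1080	Female	47.4	Conventional	1	JAK2	9	5078325		A	G	missense	His671Arg	moderate	D	D	21.7				Mesoderm commitment
1154	Female	44.1	Conventional	2	PTCH1	9	98209505	rs556901417	G	A	missense	Arg1345Cys	moderate	D	D	25.2		1.09e-04	3.89e-04	Sonic Hedgehog
1042	Female	39.5	Conventional	1	SUFU	10	104309821	rs34406289	G	A	missense	Ala138Thr	moderate	D	D	33		2.64e-05	0	Sonic Hedgehog
1141	Female	57.6	Conventional	3	SUFU	10	104375030	rs79299301	G	A	missense	Arg343His	moderate	D	D	20.8		1.58e-04	6.49e-05	Sonic Hedgehog
1006	Male	46.2	Conventional	1	PAX6	11	31823215		A	T	missense	Val98Glu	moderate	D	D	27.5				Mesoderm commitment
1162	Female	66.4	Conventional	3	EXT2	11	44254000	rs138495222	C	T	missense	Thr620Met	moderate	D	D	34	DM	9.24e-04	8.43e-04	Mesoderm commitment
1090	Female	28.3	Conventional	1	GDF3	12	7842985	rs146973734	C	T	missense	Arg195Gln	moderate	T	T	0.004	P/DM	1.85e-04	5.84e-04	Notochord development
1001	Female	47.0	Conventional	1	COL2A1	12	48380213	rs201823490	G	A	missense	Pro478Leu	moderate	D	D	23.7		0	0	Notochord development
1113	Female	27.8	Conventional	1	SOX21	13	95364265		G	C	missense	Asn13Lys	moderate	D	D	21.6				Mesoderm commitment
1050	Male	60.3	Conventional	2	WDHD1	14	55462357	rs556223202	G	A	stop_gained	Arg373*	high					8.88e-06		Mesoderm commitment
1127	Male	50.7	Conventional	3	AKT1	14	105246527	rs397514644	G	A	missense	Arg25Cys	moderate	D	T	29.6	P/DM			PI3K/AKT/mTOR
1091	Female	69.9	Conventional	2	TSC2	16	2130319		C	T	missense	Ala1184Val	moderate	D	D	24		3.56e-05		PI3K/AKT/mTOR
1028	Female	39.7	Conventional	1	TSC2	16	2136297	rs373635516	C	T	missense	Pro1589Leu	moderate	D	D	21.9		0		PI3K/AKT/mTOR
1006	Male	46.2	Conventional	1	ACACA	17	35603791		A	T	missense	Val804Glu	moderate	D	D	23.7				Mesoderm commitment
1114	Male	44.4	Conventional	1	PRKACA	19	14203391	rs41296324	A	T	stop_lost	Ter125Lysext*	high					0	2.60e-04	Mesoderm commitment
1045	Female	31.2	Conventional	1	FOXA2	20	22563180		C	T	missense	Gly234Ser	moderate	D	D	22.3				Mesoderm commitment
1098	Female	13.8	Conventional	3	SMARCB1	22	24129394		AA		frameshift	Lys13fs	high							SWI/SNF complex
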