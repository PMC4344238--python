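tf	gene_name	regulon_size	integrated_precision	integrated_recall	clr_precision	clr_recall	genie3_precision	genie3_recall
b1013	RutR	17	100	52.9	0	0	NA	NA
b3438	GntR	12	100	41.7	0	0	0	0
b4178	NsrR	83	100	3.6	NA	NA	NA	NA
b0683	Fur	129	68.6	27	0	0	0	0
b1712	IhfA	219	66.7	1.8	NA	NA	NA	NA
b0080	Cra	78	52	15	NA	NA	0	0
b3512	GadE	36	50	8.3	NA	NA	NA	NA
b1334	FNR	296	39	3	0	0	0	0
b3938	MetJ	15	30.8	26.6	0	0	NA	NA
b3094	ExuR	8	21	37.5	0	0	0	0
b3237	ArgR	37	21	35	NA	NA	NA	NA
b2369	EvgA	18	5.5	5.5	0	0	0	0
b1508	HipB	2	0.8	100	0	0	NA	NA
b3418	MalT	10	88.9	80	66.6	40	NA	NA
b3828	MetR	5	66.7	40	100	20	NA	NA
b1221	NarL	121	25	0.8	25	0.8	0	0
b0076	LeuO	20	15.5	10	8.3	5	0	0
b3569	XylR	6	80	66.6	20	16.7	100	16.7
b3868	GlnG	44	86.4	43.2	8.3	2.3	100	2.3
b0064	AraC	11	75	27	54.5	54.5	88.8	72
b0399	PhoB	60	53.3	26.7	8.3	1.7	40	3.3
b4043	LexA	59	59.57	47.5	76	32.2	61.8	35.6
b3357	Crp	497	39.4	13.5	50	0.2	22.2	0.4
b1658	PurR	31	26.1	58.1	23.5	12.9	22	35.5
b0889	Lrp	105	25	1	14.2	1.9	12.9	13.3
b1014	PutA	2	13.3	100	20	50	33.3	50
b0113	PdhR	42	10.7	7.1	71.4	11.9	100	14
b0020	NhaR	7	10.5	28.5	50	14.3	100	14.3
b3702	DnaA	12	6.8	33.3	10	16.7	3.5	16.7
b3912	CpxR	63	6.6	1.6	10.5	3.2	14.3	3.2
b2151	GalS	10	0	0	33.3	30	100	30
b2731	FhlA	30	NA	NA	9	3.3	100	3.3
b1531	MarA	38	NA	NA	40	5.3	50	5.3
b2531	IscR	32	NA	NA	38.5	15.6	31.3	15.6
b3905	RhaS	6	NA	NA	9.8	66.6	26.6	66.7
b0676	NagC	36	NA	NA	20	2.8	25	2.8
b3021	MqsA	4	NA	NA	11.1	25	20	25
b1040	CsgD	23	0	0	33	13	12.1	17.4
b3261	Fis	227	0	0	10.5	0.9	6.7	4
b1130	PhoP	55	NA	NA	20	1.8	NA	NA
b4324	UxuR	7	NA	NA	16.66	12.5	NA	NA
b1988	Nac	21	NA	NA	0	0	2.1	4.7
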