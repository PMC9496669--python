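# Degree-centrality table of the 106-target DC subnetwork (rank, target, dc)
rank	target	dc
1	AKT1	156
2	ALB	147
3	GAPDH	90
4	CASP3	88
5	EGFR	85
6	IL6	80
7	ACE	71
8	ESR1	71
9	CXCL8	65
10	APP	61
11	EP300	59
12	AR	58
13	HIF1A	58
14	HSP90AA1	54
15	CREBBP	51
16	FGF2	46
17	MAPK1	42
18	ABCB1	39
19	CASP8	39
20	GSK3B	39
21	AHR	38
22	CASP1	37
23	AKT2	36
24	COMT	35
25	CYP3A4	35
26	ACHE	34
27	CNR1	34
28	IL2	34
29	ABCG2	33
30	CTSB	33
31	NOS3	32
32	FYN	31
33	MAPK14	30
34	ADRB2	29
35	MMP9	29
36	AKR1B1	27
37	ARG1	27
38	CYP1A1	27
39	F2	27
40	CYP19A1	26
41	ESR2	26
42	IGF1R	26
43	CCR2	25
44	PPARG	25
45	CD38	24
46	CDK1	24
47	CDK5	24
48	CFTR	24
49	CYP1A2	24
50	HDAC2	24
51	MAPK8	24
52	MPO	23
53	HDAC3	22
54	ACLY	21
55	ALOX5	21
56	BACE1	21
57	CSK	20
58	CYP17A1	20
59	ELANE	20
60	F3	20
61	HDAC6	20
62	MMP2	20
63	ADCY5	19
64	ANPEP	19
65	BCHE	19
66	CDK6	19
67	CHRNA4	19
68	CYP2C9	19
69	HDAC4	19
70	HNF4A	19
71	IGFBP3	19
72	INSR	19
73	ACE2	18
74	ADORA2A	18
75	ADRB1	18
76	FLT3	18
77	GSR	18
78	HSPA1A	18
79	AKR1C3	17
80	BCL2A1	17
81	DRD2	17
82	NOS2	17
83	NR3C1	17
84	ADORA1	16
85	CHEK1	16
86	CTSL	16
87	CYP2D6	16
88	FGF1	16
89	GRIN1	16
90	MAPT	16
91	MCL1	16
92	MET	16
93	NFE2L2	16
94	PPARA	16
95	AOC3	15
96	CPB2	15
97	REN	15
98	ALDH2	14
99	ALOX15	14
100	ERN1	14
101	G6PD	14
102	LGALS3	14
103	MMP3	14
104	NOS1	14
105	NR0B2	14
106	PTGS2	14
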