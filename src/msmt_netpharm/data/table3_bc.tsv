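# Max-normalized betweenness centrality of the 32-target BC subnetwork
rank	target	bc_norm
1	AKT1	1.000000
2	GAPDH	0.961904
3	EGFR	0.631284
4	ALB	0.605009
5	CXCL8	0.564944
6	ESR1	0.531729
7	IL6	0.519001
8	CASP3	0.345339
9	HIF1A	0.344015
10	CYP1A1	0.277903
11	COMT	0.239681
12	HSP90AA1	0.227377
13	CYP3A4	0.210552
14	FGF2	0.198164
15	MAPK1	0.136887
16	MMP9	0.131470
17	F2	0.121939
18	AR	0.119210
19	GSK3B	0.111653
20	DRD2	0.106535
21	FYN	0.102145
22	NOS2	0.100364
23	HDAC2	0.089496
24	FLT3	0.084114
25	HNF4A	0.078172
26	GRIN1	0.068896
27	CASP1	0.068437
28	CYP19A1	0.067422
29	CYP2D6	0.064594
30	CNR1	0.063946
31	CYP2C9	0.058081
32	MAPK8	0.057694
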