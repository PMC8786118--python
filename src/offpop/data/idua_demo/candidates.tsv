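id	chrom	start	end	strand	sequence	source	annotation	m_i
0	chr4	996529	996552	+	GCTCTAGGCCGAAGTGTCGCAGG	published	genic:IDUA	0/0
2	chr10	118919278	118919301	+	GCTCTGGGCTGGGGTGTCGCTGG	published	genic:MIR366HG	4/0
3	chr4	148041024	148041047	+	TCTCTAGGCAGAAGTGATGCTGG	published	intergenic	4/0
4	chr8	130569488	130569511	+	GCTCTAGGCTGAAGTGCTTCTGG	published	genic:CCDC26	4/0
5	chr19	8456437	8456460	-	CCACTAGGCCAAAGTGTAGCTGG	published	genic:RAB11B	4/0
6	chr3	51437681	51437704	+	GCTCCAGGAGGAAGTGTCACAGG	published	genic:DCAF1	4/0
7	chr8	13103640	13103663	+	GTTCTAGGTGGAAGTGTTGCTGG	published	genic:DLC1	4/0
26	chr17	31707603	31707626	+	GGTCTAGGCCAAGCTGTCGCTGG	published	genic:ASIC2	4/0
9	chrU	2000	2023	-	AATCCAGGTTGAAGTGTCGCCGG	published	intergenic	.
44	chrU	4400	4423	+	AATCCAGGTTGAAGGGTCGCTGG	published	intergenic	6/0
73	chrU	7300	7323	-	TTTCTAGCCAGGACTGTCGCTGG	published	intergenic	6/0
75	chr4	89584513	89584535	+	GCTC-AGGCTGAAGGGTCGCAGG	published	genic:HERC3	2/1
76	chr19	7294878	7294900	+	GCTCTGGGACGA-GTGTCGCTGG	published	intergenic	2/1
77	chr8	47028209	47028231	+	GCTCTG-GCCGAAGTGACTCAGG	published	intergenic	.
78	chr12	111599504	111599526	+	ACTCTATGCTGA-GTGTCGCTGG	published	genic:CUX2	3/1
79	chr9	90693035	90693057	+	GAACTAGGCCGTA-TGTCGCTGG	published	intergenic	3/1
80	chrX	153618564	153618586	+	GCGCTG-GCCGCAGAGTCGCCGG	published	intergenic	.
81	chr9	125383151	125383173	+	ACT-GAGGTCGAAGTGTCGCTGG	published	intergenic	3/1
82	chr9	95886032	95886054	+	CCCCTAGGCCTAAG-GTCGCGGG	published	genic:NINJ1	3/1
84	chrX	153570255	153570277	+	GCGCT-GGCCGCAGAGTCGCCGG	published	intergenic	3/1
85	chr18	58811050	58811072	+	GCTTTAGGGCCAAG-GTCGCTGG	published	intergenic	3/1
90	chrU	9000	9024	+	ACTCTGAGgCCAAGGTGTCGCAGG	published	intergenic	5/1
116	chrU	11600	11624	+	GCTCTcAGACCATGGTGTCGCTGG	published	genic:ANKRD11	4/1
117	chrU	11700	11724	+	GCTGCAGACaCGATGTGTCGCGGG	published	intergenic	4/1
132	chrU	13200	13224	+	GCTGCGGACtCCAAGTGTCGCCGG	published	genic:LNCOC1	5/1
15	chr16	3131029	3131052	+	AATCCAGGTCGAAGGGTCGCCGG	published	intergenic	.
16	chr10	81735283	81735306	+	AATCCAGGTCGAAGGGTCGCCGG	published	intergenic	.
17	chr11	59691554	59691577	+	AATCCAGGTCGAAGGGTCGCTGG	published	intergenic	.
18	chr6	67041122	67041145	-	AATCCAGGTCGAAGGGTCGCCGG	published	intergenic	.
19	chrY	21455474	21455497	+	AATCCAGGCTGAAGGGTCGCTGG	published	intergenic	.
146	chrU	14600	14624	+	GCTCATAAGCAGGGCTGTCGCTGG	published	unknown	5/1
223	chrU	22300	22325	+	GCTCCAGGCCCTGCCTTGTCGCTGG	published	unknown	4/2
227	chrU	22700	22721	-	GCTCCCGGGCCC--TGTCGCTGG	published	unknown	5/2
265	chrU	26500	26521	-	GTACCAGTTC--AGGGTCGCAGG	published	unknown	6/2
59	chrU	5900	5923	-	GCTCTGCCCTGAGGGGTCGCAGG	published	unknown	.
97	chrU	9700	9722	+	CCTCTAGACC-AGGGGTCGCAGG	published	unknown	.
123	chrU	12300	12324	-	GTTCTTAGTCCAATGTGTCGCCGG	published	unknown	.
173	chrU	17300	17321	+	GCTGTTTGCC--AGTGTCGCTGG	published	unknown	.
273	chrU	27300	27323	+	GCTTATGCCAGTAGTGTCGCAGT	published	unknown	6/0
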