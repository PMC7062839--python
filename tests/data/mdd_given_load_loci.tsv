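snp_id	chrom	pos	nearest_gene	minor_allele	maf	q	beta1	se1	p1	or2	se2	p2
rs35591392	14	75157713	AREL1	T	0.53	2.82E-02	-0.047	0.014	8.83E-04	1.031	0.008	9.03E-05
rs78563874	11	85609073	CCDC83	T	0.24	2.76E-02	0.064	0.017	1.46E-04	0.964	0.009	9.09E-05
rs57105978	5	26843262	CDH9	T	0.03	2.02E-02	0.109	0.036	2.61E-03	0.930	0.019	1.20E-04
rs2071408	14	103987078	CKB	A	0.37	1.44E-02	0.049	0.015	1.12E-03	0.961	0.009	3.09E-06
rs7508819	20	49205320	FAM65C	T	0.58	1.94E-02	0.047	0.015	1.34E-03	1.031	0.008	1.79E-04
rs202675	11	49228613	FOLH1	C	0.28	1.79E-02	-0.054	0.016	7.43E-04	0.968	0.009	1.50E-04
rs74018295	15	57870174	GCOM1	T	0.09	1.90E-02	-0.077	0.026	3.13E-03	0.946	0.015	1.74E-04
rs111666866	6	32491925	HLA-DRB5	T	0.73	4.85E-02	0.060	0.018	8.22E-04	0.966	0.010	6.14E-04
rs4900582	14	104058014	KLC1	A	0.64	2.48E-02	0.052	0.016	8.84E-04	0.969	0.009	2.68E-04
rs8106047	19	18505741	LRRC25	A	0.16	4.31E-02	0.068	0.023	2.82E-03	0.941	0.014	1.30E-05
rs2894221	6	31461771	MICB	A	0.36	3.79E-02	-0.047	0.015	1.75E-03	0.968	0.008	7.42E-05
rs6664244	1	40374386	MYCL	T	0.36	2.47E-02	-0.057	0.015	1.32E-04	0.971	0.008	2.67E-04
rs7103992	11	48510777	OR4A47	A	0.65	2.84E-02	-0.045	0.015	2.26E-03	0.969	0.008	8.98E-05
rs10838830	11	48233932	OR4B1	A	0.35	2.42E-02	-0.044	0.015	3.06E-03	0.971	0.008	2.54E-04
rs4312096	11	48411653	OR4C5	C	0.65	1.93E-02	-0.045	0.015	2.66E-03	0.969	0.008	1.79E-04
rs3009872	1	66411400	PDE4B	T	0.43	3.87E-02	0.044	0.014	2.05E-03	1.028	0.008	4.68E-04
rs1265099	6	31105413	PSORS1C1	A	0.42	3.75E-02	0.048	0.015	1.07E-03	1.036	0.008	8.88E-06
rs6063534	20	49189168	PTPN1	T	0.51	1.80E-02	0.043	0.014	2.33E-03	1.031	0.008	1.36E-04
rs12790666	11	47983477	PTPRJ	A	0.52	1.79E-02	-0.045	0.014	1.71E-03	0.970	0.008	1.42E-04
rs12668707	7	4414425	SDK1	C	0.21	4.36E-02	-0.051	0.017	2.98E-03	1.034	0.010	5.38E-04
rs111653412	6	3370053	SLC22A23	T	0.02	2.38E-02	0.191	0.065	3.15E-03	0.863	0.040	2.47E-04
rs10157030	1	246184138	SMYD3	T	0.28	2.23E-02	0.056	0.016	5.73E-04	1.034	0.009	2.24E-04
rs6122859	20	48610609	SNAI1	A	0.63	3.99E-02	-0.047	0.015	2.12E-03	0.971	0.008	4.86E-04
rs7785189	7	12257527	TMEM106B	T	0.41	3.31E-02	-0.045	0.014	1.53E-03	1.032	0.008	7.77E-05
rs4268511	11	49046510	TRIM49B	A	0.64	1.81E-02	0.056	0.015	2.08E-04	1.032	0.008	1.32E-04
rs7949585	11	49077746	TRIM64C	T	0.60	2.00E-02	-0.051	0.015	6.11E-04	0.970	0.008	1.90E-04
rs911552	14	103999508	TRMT61A	A	0.37	8.94E-03	-0.051	0.015	5.98E-04	1.042	0.009	1.73E-06
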