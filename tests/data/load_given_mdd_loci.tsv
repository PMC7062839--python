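snp_id	chrom	pos	nearest_gene	minor_allele	maf	q	beta1	se1	p1	or2	se2	p2
rs35677603	11	47268310	ACP2	T	0.31	1.58E-03	-0.078	0.016	4.05E-07	0.985	0.009	8.59E-02
rs3017432	21	28147728	ADAMTS1	T	0.59	2.98E-03	-0.074	0.015	1.05E-06	0.982	0.008	2.84E-02
rs11823949	11	47723512	AGBL2	A	0.35	1.98E-05	-0.097	0.017	4.40E-09	0.974	0.009	3.45E-03
rs35589443	2	127847736	BIN1	A	0.03	1.43E-03	-0.265	0.052	3.65E-07	1.047	0.027	9.53E-02
rs12419692	11	47624714	C1QTNF4	A	0.35	2.81E-05	-0.087	0.015	7.21E-09	0.977	0.008	5.11E-03
rs1317149	11	47486885	CELF1	T	0.36	2.17E-05	-0.089	0.015	3.45E-09	0.980	0.008	1.43E-02
rs11576522	1	207789269	CR1	A	0.63	2.85E-04	0.079	0.015	6.56E-08	1.017	0.009	5.87E-02
rs11039138	11	47249223	DDB2	A	0.37	9.00E-03	0.070	0.015	2.45E-06	1.015	0.008	7.91E-02
rs76184771	19	18567189	ELL	A	0.13	2.03E-02	-0.091	0.021	1.29E-05	1.030	0.011	9.58E-03
rs75010292	2	55172536	EML6	A	0.11	2.63E-02	-0.098	0.023	1.72E-05	0.967	0.013	7.70E-03
rs17125924	14	53391680	FERMT2	A	0.08	2.58E-03	-0.122	0.025	6.62E-07	1.026	0.014	5.79E-02
rs4742958	9	108411944	FKTN	T	0.14	4.44E-02	-0.128	0.030	1.56E-05	0.967	0.016	3.21E-02
rs7130758	11	47749960	FNBP4	T	0.36	3.27E-05	-0.088	0.015	1.01E-08	0.978	0.009	8.73E-03
rs11021857	11	11472193	GALNT18	A	0.07	4.92E-02	0.122	0.030	3.68E-05	1.049	0.017	4.60E-03
rs9270208	6	32556402	HLA-DRB1	T	0.68	4.29E-02	-0.077	0.018	1.49E-05	1.016	0.009	8.02E-02
rs2385088	19	18545540	ISYNA1	A	0.34	3.80E-02	-0.066	0.015	1.26E-05	1.016	0.008	6.29E-02
rs3859570	19	18510925	LRRC25	T	0.41	1.26E-02	-0.069	0.016	7.84E-06	1.023	0.009	9.53E-03
rs67871383	11	47335838	MADD	T	0.32	3.53E-04	0.082	0.015	8.28E-08	1.017	0.009	4.22E-02
rs2047007	1	40427975	MFSD2A	T	0.23	4.07E-02	0.071	0.017	2.83E-05	1.027	0.009	3.42E-03
rs1125357	11	59885493	MS4A2	A	0.42	8.87E-09	0.107	0.015	3.09E-13	0.984	0.009	7.20E-02
rs1026254	11	60030457	MS4A4A	T	0.60	2.84E-10	-0.116	0.015	2.42E-15	1.014	0.008	8.87E-02
rs1582763	11	60021948	MS4A4E	A	0.36	1.40E-10	-0.123	0.015	1.19E-16	1.016	0.009	9.38E-02
rs624663	11	59945065	MS4A6A	T	0.56	1.33E-08	0.104	0.014	6.34E-13	0.984	0.008	4.91E-02
rs10838738	11	47663049	MTCH2	A	0.35	2.56E-05	0.087	0.015	5.99E-09	1.025	0.008	2.82E-03
rs61781278	1	40376741	MYCL	A	0.19	4.30E-02	0.076	0.018	1.76E-05	1.022	0.010	2.47E-02
rs11605348	11	47606483	NDUFS3	A	0.35	3.47E-06	-0.097	0.016	4.25E-10	0.978	0.009	8.36E-03
rs7105282	11	47805614	NUP160	A	0.36	4.54E-05	-0.091	0.016	1.63E-08	0.974	0.009	3.15E-03
rs541458	11	85788351	PICALM	T	0.68	1.01E-08	0.112	0.015	3.69E-13	0.984	0.010	8.07E-02
rs60075622	11	47449101	PSMC3	T	0.33	7.86E-06	0.092	0.015	1.30E-09	1.023	0.008	6.24E-03
rs755951	8	27226790	PTK2B	A	0.39	1.72E-04	-0.082	0.015	3.79E-08	1.015	0.008	6.82E-02
rs7106956	11	47458765	RAPSN	T	0.33	8.34E-06	0.092	0.015	1.28E-09	1.023	0.008	6.10E-03
rs755554	11	47432034	SLC39A13	C	0.67	4.90E-06	0.095	0.015	6.29E-10	1.024	0.009	4.71E-03
rs3781832	11	121436270	SORL1	T	0.10	2.89E-02	-0.098	0.022	1.09E-05	0.972	0.013	2.53E-02
rs67472071	11	47391745	SPI1	A	0.33	1.05E-06	-0.098	0.015	1.14E-10	0.980	0.008	1.96E-02
rs7258465	19	18533642	SSBP4	T	0.34	3.58E-02	-0.066	0.015	1.17E-05	1.017	0.008	4.36E-02
rs7011101	8	71501474	TRAM1	A	0.10	1.91E-02	-0.105	0.023	5.67E-06	1.022	0.013	9.91E-02
rs4929858	11	49070655	TRIM64C	A	0.63	2.80E-02	0.065	0.015	1.85E-05	1.036	0.008	1.85E-05
rs61781270	1	40349428	TRIT1	A	0.20	2.32E-02	0.077	0.017	7.11E-06	1.017	0.009	7.17E-02
rs66555393	8	71628753	XKR9	A	0.10	3.02E-02	0.106	0.024	9.54E-06	0.977	0.014	9.31E-02
rs17376517	3	44765221	ZNF502	T	0.05	4.63E-02	-0.141	0.033	1.65E-05	0.969	0.018	7.22E-02
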