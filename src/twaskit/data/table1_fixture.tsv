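cytoband	gene	chrom	start	end	n_snps	h2	cv_r2	p_overall	p_er_pos	p_er_neg	p_case_only
1p11.2	HIST2H2BA	1	120906028	120915073	77	0.10	0.04	3.1E-30	2.0E-32	3.6E-01	1.4E-07
1q21.1	NUDT17	1	145586804	145589439	110	0.07	0.03	1.7E-09	8.8E-10	2.4E-01	3.3E-03
2q33.1	ALS2CR12	2	202152994	202222121	363	0.35	0.03	2.2E-11	8.4E-07	2.5E-06	8.8E-01
2q33.1	CASP8	2	202098166	202152434	371	0.32	0.15	1.8E-07	8.2E-06	2.9E-04	7.6E-01
3q25.31	LINC00886	3	156465135	156534851	452	0.17	0.04	4.7E-05	1.9E-04	3.2E-03	7.3E-01
4p16.3	MAEA	4	1283639	1333925	374	0.42	0.23	3.9E-05	1.6E-04	2.3E-01	2.3E-01
5q14.2	ATG10	5	81267844	81551958	520	0.44	0.26	1.9E-10	2.4E-10	2.7E-01	2.4E-02
5q14.2	ATP6AP1L	5	81575281	81682796	467	0.62	0.51	2.3E-07	3.3E-06	2.9E-02	2.3E-01
6q14.1	RP11-250B2.5	6	81176675	81178797	402	0.12	0.08	6.9E-07	7.3E-03	5.9E-03	8.2E-01
6q22.33	RP11-73O6.3	6	130454555	130465515	557	0.33	0.11	4.5E-12	1.2E-06	5.2E-09	5.5E-02
6q22.33	L3MBTL3	6	130334844	130462594	609	0.31	0.23	8.5E-14	3.6E-08	1.8E-10	1.4E-01
10p15.1	GDI2	10	5807186	5884095	727	0.29	0.01	4.8E-07	3.1E-07	4.0E-01	2.1E-01
11p15.5	MRPL23-AS1	11	2004467	2011150	449	0.34	0.09	7.4E-06	1.4E-04	2.9E-01	2.2E-01
11q13.2	RP11-554A11.9	11	68923378	68927220	428	0.23	0.08	1.5E-06	4.9E-04	7.1E-03	6.9E-01
12q15	NUP107	12	69082742	69136785	538	0.27	0.05	6.1E-06	8.2E-07	4.3E-01	1.0E-01
15q24.3	ULK3	15	75128457	75135538	286	0.19	0.15	3.9E-05	2.1E-05	2.8E-02	5.2E-01
15q24.3	MAN2C1	15	75648133	75659986	226	0.37	0.34	7.4E-07	1.7E-04	1.8E-03	6.3E-01
15q24.3	CTD-2323K18.1	15	75819491	75893546	226	0.36	0.19	7.5E-07	3.9E-04	2.3E-03	3.1E-01
17q21.31	HSD17B1P1	17	40698782	40700724	245	0.09	0.07	1.4E-06	1.8E-03	6.4E-03	3.9E-01
17q21.32	LRRC37A4P	17	43578685	43623042	149	0.34	0.35	3.1E-10	1.4E-06	2.2E-02	8.0E-01
17q21.32	CRHR1-IT1	17	43697694	43725582	87	0.35	0.41	2.9E-10	1.8E-06	2.7E-02	8.2E-01
17q21.32	CRHR1	17	43699267	43913194	86	0.09	0.18	4.8E-08	1.8E-05	2.5E-02	7.6E-01
17q21.32	KANSL1-AS1	17	44270942	44274089	27	0.27	0.43	3.4E-10	1.4E-06	2.5E-02	7.6E-01
17q21.32	LRRC37A	17	44370099	44415160	75	0.27	0.20	7.9E-08	2.5E-05	9.7E-02	4.5E-01
17q21.32	LRRC37A2	17	44588877	44630815	130	0.37	0.18	3.1E-07	8.5E-05	8.4E-02	5.8E-01
17q22	STXBP4	17	53062975	53241646	609	0.20	0.01	1.4E-25	1.6E-25	3.3E-02	1.5E-06
19q13.2	ZNF404	19	44376515	44388203	445	0.31	0.06	2.0E-13	5.1E-12	1.7E-08	6.9E-01
19q13.2	ZNF155	19	44472014	44502477	486	0.39	0.11	8.8E-09	1.0E-07	2.0E-05	3.3E-01
19q13.2	RP11-15A1.7	19	44501048	44506988	477	0.29	0.14	9.7E-12	7.3E-10	5.1E-07	5.5E-01
20q11.23	CPNE1	20	34213953	34220170	299	0.25	0.20	5.3E-05	3.3E-04	1.4E-01	4.9E-01
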