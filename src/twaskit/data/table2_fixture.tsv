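gene	n_snps	n_sig_before	index_p	n_sig_after	index_snp	min_conditional_p	ratio	magnitude
ALS2CR12	480	12	8.2E-17	1	rs3769823	6.40E-09	0.92	1.28E-08
ATG10	619	24	6.9E-13	0	rs891159	1.20E-07	1.00	5.75E-06
ATP6AP1L	581	24	6.9E-13	0	rs891159	1.70E-07	1.00	4.06E-06
CASP8	493	12	8.2E-17	6	rs3769823	3.90E-12	0.50	2.10E-05
CRHR1	229	13	1.5E-10	0	rs17763086	1.40E-05	1.00	1.07E-05
CRHR1-IT1	230	13	1.5E-10	0	rs17763086	9.90E-05	1.00	1.52E-06
HIST2H2BA	202	19	3.5E-52	1	rs11249433	7.40E-24	0.95	4.73E-29
KANSL1-AS1	34	13	1.5E-10	0	rs17763086	1.60E-01	1.00	9.38E-10
L3MBTL3	724	13	1.7E-12	0	rs6569648	1.40E-03	1.00	1.21E-09
LRRC37A	285	13	1.5E-10	0	rs17763086	4.60E-05	1.00	3.26E-06
LRRC37A4P	285	13	1.5E-10	0	rs17763086	4.60E-05	1.00	3.26E-06
MRPL23-AS1	557	36	2.4E-33	18	rs569550	1.20E-29	0.50	2.00E-04
NUDT17	112	17	1.5E-10	0	rs36107432	3.90E-05	1.00	3.85E-06
RP11-15A1.7	594	32	1E-16	0	rs10426528	4.60E-07	1.00	2.17E-10
RP11-250B2.5	503	8	2.7E-09	0	rs9343989	1.00E-03	1.00	2.70E-06
RP11-554A11.9	532	36	2.8E-44	33	rs680618	2.80E-44	0.08	1.00E+00
RP11-73O6.3	665	13	1.7E-12	0	rs6569648	1.70E-03	1.00	1.00E-09
STXBP4	687	46	2E-28	0	rs244353	2.10E-04	1.00	9.52E-25
ZNF155	597	32	1E-16	5	rs10426528	2.00E-09	0.84	5.00E-08
ZNF404	551	32	1E-16	0	rs10426528	5.30E-07	1.00	1.89E-10
LRRC37A2	152	2	2E-08	0	rs199498	1.80E-02	1.00	1.11E-06
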