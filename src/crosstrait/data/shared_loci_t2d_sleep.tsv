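Trait2	Locus_No	SNP	Gene	Chr:Pos	A1/A2	Z1	Z2	ConjFDR	P1	P2
insomnia	1	rs2820290	NAV1	1:201783682	A/G	-3.90	-4.62	0.01	9.69e-5	3.88e-6
insomnia	1	rs2820290	IPO9-AS1	1:201783682	A/G	-3.90	-4.62	0.01	9.69e-5	3.88e-6
insomnia	2	rs4688760	RBM6	3:49980596	C/T	-5.67	-4.42	0.01	1.44e-8	9.82e-6
insomnia	3	rs67073213	Upstream: SPATA18;Downstream: RP11-588F10.1	4:53286872	A/G	3.87	-4.48	0.01	1.10e-4	7.57e-6
insomnia	4	rs26434	PAM	5:102363402	C/T	5.90	-4.40	0.01	3.58e-9	1.10e-5
insomnia	5	rs4526367	MSRA	8:10213462	G/A	-4.96	5.49	0.00	7.10e-7	3.99e-8
insomnia	6	rs4735334	NDUFAF6	8:95955292	G/A	3.98	4.63	0.01	6.91e-5	3.70e-6
insomnia	6	rs4735334	TP53INP1	8:95955292	G/A	3.98	4.63	0.01	6.91e-5	3.70e-6
sleep_duration	7	rs4949329	PUM1	1:31440361	T/C	-4.04	4.78	0.00	5.29e-5	1.80e-6
sleep_duration	8	rs61780511	Upstream: PUM1;Downstream: SEPW1P	1:31546006	G/A	3.83	-4.12	0.01	1.27e-4	3.81e-5
sleep_duration	9	rs12137232	LMOD1	1:201885446	T/G	-3.90	4.36	0.01	9.69e-5	1.30e-5
sleep_duration	10	rs6711622	DNMT3A	2:25531350	A/G	-3.85	4.14	0.01	1.19e-4	3.51e-5
sleep_duration	11	rs1641155	LINC01122	2:58965211	G/T	4.69	4.90	0.00	2.75e-6	9.36e-7
sleep_duration	12	rs12485697	Upstream: RP11-231I13.2;Downstream: COX6CP6	3:70543116	T/C	3.89	-4.16	0.01	1.01e-4	3.15e-5
sleep_duration	13	rs9844666	PCCB	3:135974216	A/G	4.19	4.60	0.00	2.77e-5	4.27e-6
sleep_duration	14	rs1291921	PCCB	3:136036226	A/G	-4.35	-4.50	0.00	1.36e-5	6.85e-6
sleep_duration	15	rs11242483	PAM	5:102323766	T/C	6.07	6.28	0.00	1.31e-9	3.39e-10
sleep_duration	16	rs329124	JADE2	5:133865452	G/A	5.14	-4.65	0.00	2.80e-7	3.30e-6
sleep_duration	17	rs62442924	MAD1L1	7:1989976	T/C	-4.15	5.16	0.00	3.33e-5	2.47e-7
sleep_duration	18	rs7790729	AUTS2	7:69598649	T/C	3.76	4.07	0.01	1.69e-4	4.77e-5
sleep_duration	19	rs3121426	Upstream: 5-Mar;Downstream: MARK2P9	10:94153435	T/G	-6.69	-4.29	0.00	2.19e-11	1.82e-5
sleep_duration	20	rs11037564	HSD17B12	11:43708725	C/T	-3.77	5.01	0.01	1.65e-4	5.41e-7
sleep_duration	21	rs174533	MYRF	11:61549025	A/G	-3.90	4.44	0.01	9.69e-5	8.82e-6
sleep_duration	21	rs174533	TMEM258	11:61549025	A/G	-3.90	4.44	0.01	9.69e-5	8.82e-6
sleep_duration	22	rs12820906	PITPNM2	12:123493123	G/A	-5.41	4.11	0.01	6.39e-8	3.90e-5
sleep_duration	23	rs12433645	NRXN3	14:80028314	T/C	-4.30	-4.12	0.01	1.75e-5	3.75e-5
sleep_duration	24	rs4780887	PDILT	16:20393562	C/A	-3.92	4.23	0.01	8.78e-5	2.39e-5
sleep_duration	25	rs8047587	FTO	16:53798622	T/G	16.19	-6.66	0.00	6.29e-59	2.66e-11
chronotype	26	rs148262742	Upstream: CDKN2C;Downstream: MIR4421	1:51472241	C/T	-5.34	-3.95	0.01	9.40e-8	7.93e-5
chronotype	27	rs12140153	INADL	1:62579891	T/G	-5.18	-6.10	0.00	2.21e-7	1.03e-9
chronotype	28	rs903518	UBE2E2	3:23336968	G/A	-3.93	-4.22	0.00	8.32e-5	2.42e-5
chronotype	29	rs78580841	CCDC12	3:46986452	T/C	4.05	4.78	0.00	5.03e-5	1.72e-6
chronotype	30	rs1679147	MRAS	3:138097537	A/G	4.45	-3.93	0.01	8.72e-6	8.49e-5
chronotype	31	rs17774982	ST6GAL1	3:186684460	C/T	-4.88	-4.51	0.00	1.07e-6	6.39e-6
chronotype	32	rs1296328	RP11-775H9.2	4:137083193	A/C	4.98	6.11	0.00	6.37e-7	9.73e-10
chronotype	33	rs1265945	EHMT2	6:31861815	G/A	-4.10	4.71	0.00	4.15e-5	2.51e-6
chronotype	34	rs734597	Upstream: RPS17P5;Downstream: RP4-753D5.3	6:50836279	A/G	6.06	5.12	0.00	1.35e-9	2.99e-7
chronotype	35	rs4434471	Upstream: FTH1P5;Downstream: RP3-437C15.2	6:51146875	G/A	4.02	4.37	0.00	5.94e-5	1.24e-5
chronotype	36	rs66930764	Upstream: RP5-826L7.1;Downstream: RP1-230L10.1	6:164103243	A/G	-5.02	-4.38	0.00	5.24e-7	1.21e-5
chronotype	37	rs11555134	GRB10	7:50659193	T/C	4.30	-5.30	0.00	1.75e-5	1.17e-7
chronotype	38	rs77655131	ORAI2	7:102086552	T/C	4.94	-5.54	0.00	7.70e-7	3.03e-8
chronotype	39	rs11496066	FBXL13	7:102486254	C/T	-5.18	5.90	0.00	2.21e-7	3.62e-9
chronotype	40	rs62482405	PSMC2	7:102987583	G/T	4.36	-4.09	0.01	1.29e-5	4.23e-5
chronotype	41	rs3808478	TRPS1	8:116678277	C/T	-4.00	4.86	0.00	6.43e-5	1.15e-6
chronotype	42	rs6559752	C9orf64	9:86570075	T/C	-3.80	4.17	0.01	1.44e-4	3.09e-5
chronotype	43	rs6478623	DENND1A	9:126315123	G/T	3.88	-4.68	0.01	1.06e-4	2.81e-6
chronotype	44	rs11145756	SEC16A	9:139364585	G/A	-4.63	4.09	0.01	3.64e-6	4.24e-5
chronotype	45	rs10998304	TET1	10:70342775	C/T	4.08	-4.36	0.00	4.41e-5	1.28e-5
chronotype	46	rs143539037	CPEB3	10:93827055	T/C	5.92	-3.92	0.01	3.26e-9	8.80e-5
chronotype	47	rs11039307	Upstream: FAM180B;Downstream: C1QTNF4	11:47611152	T/C	5.22	4.83	0.00	1.77e-7	1.37e-6
chronotype	48	rs11039358	FNBP4	11:47746962	G/A	4.52	4.30	0.00	6.10e-6	1.72e-5
chronotype	49	rs4237555	Upstream: MTNR1B;Downstream: RPL26P31	11:92725803	C/T	-7.86	-4.85	0.00	3.84e-15	1.22e-6
chronotype	50	rs4606726	PDILT	16:20383700	G/A	-3.83	-3.97	0.01	1.27e-4	7.10e-5
chronotype	51	rs8047587	FTO	16:53798622	T/G	16.19	7.42	0.00	6.29e-59	1.19e-13
chronotype	52	rs217184	TXNL4B	16:72105965	C/T	-3.98	4.06	0.01	6.91e-5	4.99e-5
chronotype	52	rs217184	HPR	16:72105965	C/T	-3.98	4.06	0.01	6.91e-5	4.99e-5
chronotype	53	rs3816511	PEMT	17:17409401	G/A	3.77	4.79	0.01	1.61e-4	1.63e-6
chronotype	54	rs1371319	Upstream: RP11-687D19.1;Downstream: RN7SKP182	18:36277087	C/T	4.50	4.22	0.00	6.94e-6	2.45e-5
chronotype	55	rs17596995	TCF4	18:53166594	A/G	-4.25	-4.94	0.00	2.12e-5	7.66e-7
chronotype	56	rs5762622	TTC28	22:28835458	A/G	4.28	-4.32	0.00	1.87e-5	1.57e-5
chronotype	57	rs5757906	TNRC6B	22:40687757	C/T	-3.91	-4.27	0.00	9.24e-5	1.91e-5
chronotype	58	rs28741121	XRCC6	22:42025823	A/G	-4.07	-4.19	0.00	4.72e-5	2.74e-5
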