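gene	shm_indicator	total_snvs	mutated_samples	titv_ratio	titv_p	motif_enrichment	motif_p	cg_at_enrichment	cg_at_p	rpkm_fold_change	avg_rpkm_tumor	avg_rpkm_normal	previously_reported
BCL6	0.1389	179	27	1.27	0.06	1.41	0.0919	0.77	0.5	0.55739	61.4600	160.93086	1
BCL2	0.2642	146	11	0.8	0.5	1.47	0.0738	0.79	0.5	1.29298	20.7300	2.59639	1
BTG2	0.0123	55	18	1.04	0.45	2.78	0.0002	1.05	0.0172	-0.27272	149.6800	223.5928	0
TMSB4X	0.0201	52	17	0.79	0.5	1.69	0.1114	1.41	0.0001	0.11158	1485.8800	1017.2736	0
ZFP36L1	0.0000	52	16	1.17	0.29	4.18	0	1.26	0.0009	0.05879	50.4900	142.76265	0
RHOH	0.0509	42	17	0.68	0.5	2.91	0.0005	0.81	0.5	0.01346	76.7300	352.06877	1
SERPINA9	0.1296	36	7	0.57	0.5	2.15	0.0345	1.03	0.1261	5.48905	277.4700	237.10067	0
CD83	0.0006	34	8	1.13	0.37	3.49	0.0001	1.67	0	1.08042	162.1900	478.47502	0
SGK1	0.0000	34	5	0.62	0.5	5.5	0	1.37	0.0103	0.1586	2.9000	4.48411	0
BCL7A	0.0083	32	14	1.46	0.14	4.29	0	0.9	0.5	0.73039	31.1700	96.05465	1
BACH2	0.5000	30	8	0.25	0.5	0.67	0.5	0.75	0.5	0.30362	8.0700	52.5643	0
LTB	0.0794	23	10	1.3	0.27	2.72	0.0156	1.15	0.1208	1.81466	142.6400	189.28412	0
BIRC3	0.1158	21	12	1.1	0.41	2.03	0.0975	1.4	0.0385	-0.10012	80.9500	175.95683	0
HIST1H2AC	0.0009	19	9	1.71	0.13	4.95	0	1.47	0.0123	0	0.2000	0.08058	0
TCL1A	0.2012	17	8	0.55	0.5	1.03	0.4869	1.48	0.0335	-0.07685	248.7300	709.73845	0
ST6GAL1	0.2318	15	8	0.88	0.5	2.17	0.1233	1.03	0.202	0.23782	64.4800	149.40245	1
CD74	0.0032	14	8	0.56	0.5	5.18	0	1.7	0.0061	0.44198	10559.9000	8227.8865	0
SOCS1	0.0272	14	5	1.33	0.3	3.3	0.0117	1.38	0.0058	0.16955	26.1800	39.5316	1
IRF8	0.2448	13	9	1.6	0.2	1.19	0.4275	1.14	0.1694	-0.0691	174.1000	462.84745	0
BTG1	0.0683	13	9	1.17	0.39	3.55	0.0076	1.22	0.1065	0.12187	191.6600	975.71198	0
CR607557	0.0008	13	9	1.6	0.2	6.69	0	1.11	0.2004	0	0.0000	0	0
LRMP	0.2823	13	7	0.63	0.5	1.08	0.4667	1.48	0.0965	0.22716	149.9900	276.99144	1
IRF4	0.0208	13	4	5.5	0.01	2.63	0.0714	1.28	0.0201	1.82701	106.0800	29.07161	1
CIITA	0.0003	12	9	1	0.5	6.29	0	1.78	0.001	0.49221	25.6600	23.75111	1
DTX1	0.0294	12	8	3	0.04	3.71	0.0059	1.26	0.1041	0.42032	87.7300	151.20776	0
CXCR4	0.0025	12	7	0.71	0.5	5.9	0	1.68	0.002	0.42432	143.9600	968.41417	0
PIM1	0.0146	12	7	1	0.5	4.6	0.0003	1.47	0.0255	0.96916	84.0200	165.35743	1
S1PR2	0.0183	11	7	1.75	0.18	5.25	0.0005	1.19	0.0689	0.59678	22.3300	96.04705	0
MALAT1	0.1786	11	7	1.2	0.38	2.6	0.0729	1.21	0.2048	0	0.0000	0	0
SPRED2	0.2356	11	6	0.57	0.5	2.89	0.0523	0.75	0.5	1.46507	12.2400	22.09212	0
PAX5	0.0114	10	7	1.5	0.26	6.39	0.0001	1.39	0.0726	-0.2793	52.5200	127.01243	1
DMD	0.0239	10	3	2.33	0.1	3.36	0.0301	2.28	0.0044	1.50279	10.5300	3.6875	0
LLT1	0.2591	10	3	2.33	0.1	1.49	0.338	0.49	0.5	-0.21925	47.9800	86.73398	0
ETS1	0.1877	9	8	0.5	0.5	2.08	0.2211	1.61	0.0598	0.40109	58.3700	102.81003	0
DUSP2	0.0040	9	4	2	0.16	6.18	0	1.18	0.0532	0.65633	119.7600	160.9238	0
AK123543	0.0609	8	5	0	0.5	4.1	0.0127	1.71	0.0355	0	0.0000	0	0
POU2AF1	0.5000	7	6	0.75	0.5	0	0.5	0.61	0.5	-0.12034	153.9300	429.77219	0
GADD45B	0.1136	7	6	6	0.03	2.58	0.1562	0.93	0.3192	-0.04866	30.9900	132.9862	0
MS4A1	0.1944	7	4	6	0.03	0	0.5	0.66	0.5	0.03938	644.0700	715.41695	0
P2RY8	0.3182	7	3	1.33	0.35	2.34	0.1826	0.92	0.5	0	0.4900	1.30263	0
GRHPR	0.1429	6	5	2	0.21	0	0.5	1.81	0.0282	-0.17425	57.6200	27.42158	0
NCOA3	0.1770	6	4	5	0.05	0	0.5	1.39	0.2165	0.22822	42.8100	76.49762	0
UBE2J1	0.0140	6	3	6	0.01	5.29	0.0032	1.57	0.1199	-0.31589	67.8200	239.48779	0
MYC	0.0630	6	3	1	0.5	5.38	0.0029	1.42	0.1713	0.63538	22.5300	27.42303	1
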