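# element Ar  Z=18  A=39.948  K_edge_keV=3.2029
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	5585.46	5579.05	6.4091	0.00245975	5557.53
1.05665	4780.09	4773.68	6.39889	0.00273839	4756.18
1.1165	4088.55	4082.16	6.38755	0.00304765	4068.11
1.17974	3495.18	3488.81	6.37495	0.00339068	3477.71
1.24657	2986.4	2980.03	6.36096	0.00377088	2971.47
1.31718	2550.42	2544.07	6.34543	0.00419196	2537.67
1.39179	2177.07	2170.74	6.32821	0.00465789	2166.18
1.47063	1857.55	1851.23	6.30914	0.00517295	1848.26
1.5	1754.51	1748.21	6.3018	0.00537064	1745.74
1.55394	1583.96	1577.66	6.28802	0.00574173	1576.04
1.64196	1349.26	1342.99	6.26466	0.00636906	1342.51
1.73497	1148.59	1142.35	6.23885	0.00706009	1142.35
1.83325	977.578	971.359	6.21037	0.00782017	971.359
1.93709	832.244	826.056	6.17898	0.00865491	826.057
2	758.289	752.121	6.15933	0.00917556	752.121
2.04682	706.426	700.272	6.14442	0.00957003	700.272
2.16276	583.239	577.122	6.10644	0.0105714	577.123
2.28527	472.917	466.84	6.06478	0.0116648	466.841
2.41472	383.297	377.265	6.01914	0.012856	377.265
2.5515	316.047	310.064	5.96927	0.0141506	310.064
2.69603	269.83	263.899	5.91487	0.0155538	263.899
2.84875	242.775	236.903	5.8557	0.0170702	236.903
3	234.25	228.436	5.79555	0.0186007	228.436
3.01012	234.365	228.555	5.79148	0.0187039	228.555
3.18062	266.488	260.745	5.72198	0.020458	260.745
3.36079	354.614	348.944	5.647	0.0223347	326.829
3.55116	498.945	493.354	5.56636	0.0243347	463.762
3.75232	670.648	665.142	5.47993	0.0264576	627.385
3.96487	778.05	772.633	5.38763	0.0287014	731.126
4	780.642	775.24	5.3723	0.0290716	733.958
4.18946	745.068	739.747	5.28944	0.0310623	702.137
4.42677	644.536	639.317	5.18542	0.0335351	608.555
4.67753	534.047	528.935	5.07568	0.0361128	504.849
4.94249	448.753	443.754	4.96041	0.038787	424.63
5	435.749	430.774	4.93553	0.0393599	412.423
5.22245	394.952	390.578	4.3318	0.0415481	374.648
5.51828	351.726	348.899	2.78245	0.0443853	335.432
5.83086	311.827	310.321	1.45854	0.0472871	298.986
6	290.966	289.699	1.21874	0.0488146	279.415
6.16115	271.301	270.012	1.2382	0.0502419	260.678
6.51015	231.209	229.698	1.45759	0.0532383	222.184
6.87892	194.503	192.649	1.79754	0.0562651	186.684
7.26858	162.793	160.608	2.12552	0.0593125	155.903
7.68031	136.634	134.246	2.32574	0.0623715	130.524
8	120.794	118.397	2.33303	0.0646388	115.245
8.11536	115.868	113.499	2.30311	0.0654348	110.521
8.57506	99.0437	96.8809	2.09431	0.0684963	94.4755
9.06079	84.9413	83.0583	1.81145	0.0715514	81.1069
9.57404	72.8889	71.2719	1.54244	0.0745968	69.6875
10	64.5003	63.0343	1.38898	0.0769939	61.6931
10.1164	62.4189	60.9824	1.35883	0.0776296	59.6999
10.6894	53.3762	52.0684	1.22717	0.0806479	51.0325
11.2949	45.623	44.4269	1.11244	0.0836495	43.5908
11.9347	38.9794	37.8816	1.01115	0.086632	37.2075
12.6108	33.29	32.2802	0.920259	0.0895921	31.737
13.3251	28.4204	27.4908	0.837118	0.0925257	27.0536
14.0799	24.2547	23.3998	0.759491	0.0954272	23.0483
14.8775	20.693	19.9092	0.68553	0.0982897	19.6268
15	20.2089	19.4355	0.674736	0.098712	19.1622
15.7202	17.6445	16.9289	0.614509	0.101105	16.7024
16.6107	15.0333	14.3814	0.548072	0.103863	14.2001
17.5516	12.8034	12.2093	0.487529	0.106555	12.0645
18.5458	10.9038	10.3608	0.433826	0.109168	10.2455
19.5963	9.28924	8.78996	0.387581	0.111693	8.69837
20	8.75577	8.27074	0.372431	0.112602	8.18671
20.7063	7.91669	7.45453	0.348041	0.114117	7.3821
21.8793	6.74345	6.31543	0.311588	0.116431	6.25851
23.1186	5.74293	5.34594	0.278368	0.118625	5.30157
24.4282	4.89202	4.52259	0.248737	0.120692	4.48838
25.8119	4.17002	3.8245	0.222891	0.122625	3.79852
27.274	3.55855	3.23324	0.200891	0.12442	3.21393
28.819	3.04147	2.73272	0.182681	0.126072	2.71885
30	2.7159	2.41701	0.171713	0.127185	2.40646
30.4514	2.60455	2.30895	0.168023	0.127579	2.29952
32.1763	2.23288	1.9489	0.155037	0.128942	1.94314
33.999	1.91655	1.64345	0.142942	0.130161	1.64071
35.9249	1.64798	1.38511	0.13163	0.131235	1.3849
37.9598	1.42042	1.16724	0.121014	0.132167	1.16914
40	1.23678	0.992345	0.111508	0.132923	0.995951
40.1101	1.22792	0.983941	0.111023	0.132959	0.987629
42.3821	1.06477	0.829801	0.101352	0.133613	0.835019
44.7828	0.925839	0.699738	0.0919706	0.134131	0.706283
47.3196	0.807186	0.589582	0.0830892	0.134515	0.597298
50	0.705549	0.495929	0.0748537	0.134767	0.504693
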