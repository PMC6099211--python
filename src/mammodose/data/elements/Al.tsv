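# element Al  Z=13  A=26.982  K_edge_keV=1.5596
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	1185	1183.57	1.42719	0.00517068	1179.07
1.05665	1030.46	1029.03	1.42277	0.00572312	1025.31
1.1165	893.808	892.384	1.4179	0.00632888	889.339
1.17974	773.529	772.109	1.41254	0.00699189	769.661
1.24657	668.109	666.695	1.40665	0.00771608	664.769
1.31718	576.072	574.663	1.40019	0.00850538	573.191
1.39179	496.001	494.599	1.39312	0.00936361	493.521
1.47063	426.565	425.17	1.38538	0.0102944	424.432
1.5	404	402.607	1.38244	0.0106468	401.98
1.55394	365.842	364.454	1.37695	0.0113012	364.013
1.55944	362.202	360.815	1.37638	0.0113685	360.391
1.55976	3956.16	3954.78	1.37635	0.0113723	3877.06
1.64196	3544.9	3543.52	1.36777	0.012387	3477.37
1.73497	3141.52	3140.15	1.3578	0.0135544	3084.67
1.83325	2774.58	2773.21	1.34701	0.0148054	2726.85
1.93709	2441.55	2440.2	1.33536	0.0161415	2401.59
2	2263	2261.65	1.3282	0.0169558	2226.99
2.04682	2139.93	2138.59	1.32282	0.0175634	2106.56
2.16276	1866.92	1865.59	1.30936	0.0190712	1839.15
2.28527	1622.28	1620.97	1.29496	0.0206641	1599.23
2.41472	1405.35	1404.05	1.2796	0.0223408	1386.22
2.5515	1214.73	1213.45	1.26329	0.0240993	1198.87
2.69603	1048.58	1047.31	1.24602	0.025937	1035.4
2.84875	904.741	903.485	1.22781	0.0278511	893.764
3	788	786.76	1.20986	0.029715	778.722
3.01012	780.968	779.73	1.20867	0.0298385	771.79
3.18062	673.853	672.632	1.18862	0.0318964	666.151
3.36079	580.649	579.448	1.16771	0.0340222	574.163
3.55116	499.781	498.598	1.14596	0.0362139	494.295
3.75232	429.795	428.633	1.12343	0.0384704	425.132
3.96487	369.369	368.228	1.10014	0.0407915	365.381
4	360.5	359.362	1.09635	0.0411691	356.609
4.18946	317.205	316.085	1.07616	0.0431778	313.773
4.42677	272.118	271.021	1.05151	0.0456311	269.144
4.67753	233.243	232.168	1.02625	0.0481543	230.647
4.94249	199.799	198.748	1.00042	0.0507508	197.516
5	193.4	192.354	0.994923	0.0513056	191.175
5.22245	171.058	170.03	0.97404	0.0534244	169.033
5.51828	146.34	145.337	0.94715	0.0561793	144.53
5.83086	125.105	124.127	0.919776	0.0590193	123.475
6	115.3	114.334	0.905387	0.0605277	113.751
6.16115	106.883	105.929	0.891942	0.0619474	105.403
6.51015	91.2632	90.3346	0.863673	0.0649656	89.91
6.87892	77.8852	76.9822	0.834992	0.0680741	76.64
7.26858	66.4368	65.5596	0.805929	0.0712715	65.2841
7.68031	56.647	55.7959	0.776516	0.0745538	55.5743
8	50.33	49.4984	0.754544	0.0770342	49.3099
8.11536	48.2807	47.456	0.746793	0.0779146	47.278
8.57506	41.1259	40.3277	0.716812	0.0813448	40.1849
9.06079	35.0128	34.2414	0.686633	0.0848327	34.127
9.57404	29.798	29.0533	0.656329	0.088364	28.9619
10	26.23	25.5065	0.632356	0.0911737	25.43
10.1164	25.3553	24.6417	0.621705	0.0919222	24.5688
10.6894	21.5667	20.8983	0.572843	0.0954888	20.8403
11.2949	18.337	17.7109	0.527072	0.0990442	17.6649
11.9347	15.5875	15.0005	0.484393	0.102568	14.9642
12.6108	13.2495	12.6987	0.444786	0.106039	12.6703
13.3251	11.2635	10.7459	0.408204	0.109439	10.7239
14.0799	9.57798	9.09065	0.374578	0.112747	9.07379
14.8775	8.14837	7.68861	0.343814	0.115948	7.67594
15	7.955	7.49911	0.339472	0.116414	7.487
15.7202	6.93257	6.49797	0.315578	0.119027	6.48873
16.6107	5.89588	5.48448	0.289432	0.121972	5.47806
17.5516	5.01612	4.626	0.265347	0.124773	4.6219
18.5458	4.27262	3.90192	0.243275	0.127424	3.89975
19.5963	3.64645	3.29339	0.223144	0.129921	3.29283
20	3.441	3.09403	0.216169	0.130805	3.094
20.7063	3.11835	2.78131	0.20478	0.13226	2.78211
21.8793	2.66703	2.3448	0.187782	0.134442	2.34678
23.1186	2.28245	1.97393	0.172057	0.136466	1.97693
24.4282	1.95604	1.66016	0.157538	0.138334	1.66407
25.8119	1.6799	1.3957	0.144155	0.140047	1.40041
27.274	1.44695	1.1735	0.131837	0.141607	1.17895
28.819	1.25087	0.987341	0.120516	0.143016	0.993472
30	1.128	0.871199	0.112852	0.143949	0.8778
30.4514	1.08603	0.831635	0.110122	0.144276	0.838406
32.1763	0.945535	0.699567	0.100581	0.145387	0.706949
33.999	0.825604	0.587445	0.0918085	0.14635	0.595419
35.9249	0.723741	0.492847	0.0837265	0.147167	0.501399
37.9598	0.63763	0.413523	0.0762696	0.147838	0.422642
40	0.5685	0.350447	0.0697117	0.148341	0.3601
40.1101	0.565179	0.347435	0.0693808	0.148364	0.357115
42.3821	0.503865	0.292086	0.0630321	0.148747	0.302326
44.7828	0.451475	0.245284	0.0572027	0.148989	0.256084
47.3196	0.406607	0.205657	0.0518588	0.149091	0.217018
50	0.3681	0.172075	0.0469678	0.149057	0.184
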