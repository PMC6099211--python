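# element Ca  Z=20  A=40.078  K_edge_keV=4.0381
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	7.8779	0.106477	7.76595	0.00547777	0.106487
1.05665	7.78455	0.0366779	7.74185	0.00602011	0.0366903
1.1165	7.73807	0.0159316	7.71553	0.0066067	0.0159459
1.17974	7.70266	0.00856825	7.68686	0.00723947	0.00858488
1.24657	7.6692	0.0056048	7.65567	0.00792018	0.00562401
1.31718	7.63488	0.0043823	7.62184	0.00865038	0.00440447
1.39179	7.59869	0.0040267	7.58524	0.00943142	0.00405224
1.47063	7.56026	0.00427693	7.54572	0.0102644	0.00430628
1.5	7.54589	0.00451368	7.5308	0.0105762	0.00454452
1.55394	7.51949	0.00516754	7.50317	0.0111503	0.00520122
1.64196	7.47657	0.00699282	7.45749	0.0120898	0.00703139
1.73497	7.4321	0.0104401	7.40858	0.0130836	0.0104842
1.83325	7.38743	0.016949	7.35635	0.0141322	0.0169993
1.93709	7.34548	0.0295081	7.30073	0.0152362	0.0295654
2	7.32461	0.041806	7.2669	0.0159023	0.0418677
2.04682	7.31244	0.0543655	7.24168	0.0163964	0.0544306
2.16276	7.30141	0.104664	7.17913	0.0176138	0.104738
2.28527	7.33994	0.207983	7.11306	0.0188897	0.208067
2.41472	7.48531	0.421647	7.04343	0.020226	0.421742
2.5515	7.85445	0.862614	6.97021	0.0216251	0.862721
2.69603	8.67938	1.76292	6.89338	0.0230897	1.76304
2.84875	10.4036	3.56609	6.81288	0.0246235	3.56623
3	13.5561	6.79608	6.73394	0.0261301	6.79623
3.01012	13.8373	7.08234	6.72869	0.0262304	7.08249
3.18062	20.3945	13.7258	6.64074	0.027915	13.726
3.36079	32.4481	25.8694	6.54895	0.0296819	25.8696
3.55116	47.0936	40.6088	6.45326	0.0315361	40.609
3.75232	64.3511	57.9641	6.35357	0.0334823	57.9643
3.96487	77.3859	71.1006	6.24977	0.035525	71.1009
4	78.2337	71.965	6.23276	0.0358612	71.9653
4.0377	78.1876	71.9368	6.21456	0.0362216	71.9371
4.0385	637.572	631.321	6.21417	0.0362293	570.495
4.18946	636.533	630.354	6.14175	0.0376679	571.809
4.42677	579.009	572.94	6.02943	0.039914	522.58
4.67753	502.152	496.197	5.9127	0.0422652	454.921
4.94249	438.96	433.124	5.79151	0.0447219	399.026
5	429.397	423.586	5.76549	0.0452511	390.622
5.22245	392.562	387.444	5.07103	0.0472832	358.577
5.51828	350.938	347.621	3.26711	0.0499465	323.11
5.83086	347.451	345.68	1.7183	0.0527075	322.613
6	340.954	339.461	1.43843	0.0541769	317.448
6.16115	331.147	329.627	1.46397	0.0555602	308.811
6.51015	300.017	298.229	1.72993	0.0584972	280.405
6.87892	262.436	260.232	2.14185	0.0615096	245.513
7.26858	225.851	223.244	2.54293	0.0645876	211.294
7.68031	193.273	190.411	2.79388	0.0677205	180.766
8	172.649	169.767	2.81113	0.0700682	161.511
8.11536	166.111	163.262	2.77802	0.0708973	155.435
8.57506	143.345	140.735	2.53637	0.074107	134.35
9.06079	123.778	121.498	2.20246	0.0773388	116.282
9.57404	106.751	104.788	1.88258	0.0805829	100.53
10	94.7625	92.9791	1.70026	0.0831484	89.3628
10.1164	91.7697	90.0212	1.66462	0.0838301	86.5603
10.6894	78.7169	77.1212	1.50871	0.0870721	74.3156
11.2949	67.4609	65.9982	1.37236	0.0903018	63.7265
11.9347	57.7696	56.4245	1.25155	0.093513	54.587
12.6108	49.438	48.1986	1.14273	0.0966998	46.7137
13.3251	42.2851	41.1425	1.04277	0.0998568	39.9436
14.0799	36.1519	35.0999	0.949007	0.102979	34.1326
14.8775	30.8992	29.9339	0.859231	0.10606	29.1539
15	30.1848	29.2322	0.846089	0.106515	28.4769
15.7202	26.3969	25.5153	0.772587	0.109094	24.8869
16.6107	22.5324	21.7291	0.691191	0.112073	21.2235
17.5516	19.2235	18.4917	0.616757	0.11499	18.0854
18.5458	16.3964	15.7281	0.550544	0.117836	15.402
19.5963	13.9857	13.3716	0.493415	0.1206	13.1104
20	13.1871	12.5908	0.474686	0.121601	12.3503
20.7063	11.93	11.3622	0.444489	0.123273	11.1533
21.8793	10.1708	9.64579	0.399198	0.125844	9.47917
23.1186	8.66853	8.18247	0.357761	0.128301	8.05003
24.4282	7.38848	6.93717	0.320672	0.130637	6.83233
25.8119	6.29984	5.87878	0.288224	0.13284	5.7962
27.274	5.37538	4.97993	0.260542	0.134904	4.91534
28.819	4.59122	4.2168	0.2376	0.136821	4.16673
30	4.09601	3.7341	0.223783	0.138124	3.69286
30.4514	3.9264	3.56868	0.219133	0.138588	3.53039
32.1763	3.36009	3.01717	0.202725	0.140199	2.98844
33.999	2.87771	2.54869	0.187375	0.141653	2.52775
35.9249	2.4677	2.1518	0.172955	0.142949	2.13721
37.9598	2.11979	1.81634	0.159363	0.144087	1.80693
40	1.83849	1.54632	0.147143	0.145023	1.54098
40.1101	1.82491	1.53333	0.146519	0.145068	1.52818
42.3821	1.57475	1.29483	0.134029	0.145895	1.29319
44.7828	1.36179	1.09337	0.12186	0.146568	1.09466
47.3196	1.17997	0.92258	0.110298	0.147092	0.926334
50	1.02426	0.777251	0.0995445	0.147467	0.783104
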