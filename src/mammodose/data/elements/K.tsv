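# element K  Z=19  A=39.098  K_edge_keV=3.6074
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	11.904	4.70439	7.19461	0.00497875	4.7044
1.05665	8.55496	1.37539	7.17412	0.00544752	1.3754
1.1165	7.65992	0.502096	7.15187	0.00595149	0.502109
1.17974	7.3595	0.225251	7.12776	0.00649213	0.225266
1.24657	7.231	0.122252	7.10168	0.00707092	0.12227
1.31718	7.16027	0.0790457	7.07354	0.00768938	0.0790654
1.39179	7.11157	0.0599754	7.04324	0.00834912	0.059998
1.47063	7.07235	0.0526161	7.01069	0.00905186	0.052642
1.5	7.05962	0.0518656	6.99843	0.00931489	0.0518928
1.55394	7.03818	0.0526051	6.97578	0.00979954	0.0526347
1.64196	7.00811	0.0590955	6.93842	0.0105944	0.0591293
1.73497	6.98353	0.0735695	6.89852	0.0114388	0.0736081
1.83325	6.96845	0.100142	6.85598	0.0123359	0.100186
1.93709	6.97108	0.147111	6.81068	0.0132889	0.147161
2	6.98642	0.189464	6.78309	0.0138688	0.189517
2.04682	7.0071	0.230294	6.76251	0.0143017	0.230351
2.16276	7.10623	0.379506	6.71135	0.0153785	0.379571
2.28527	7.32409	0.650506	6.65706	0.0165241	0.650579
2.41472	7.76369	1.14646	6.59949	0.0177439	1.14654
2.5515	8.61217	2.05464	6.53848	0.0190431	2.05474
2.69603	10.1994	3.70515	6.47385	0.0204277	3.70525
2.84875	13.0839	6.6566	6.40541	0.0219036	6.65672
3	17.7663	11.4054	6.3375	0.0233774	11.4055
3.01012	18.1619	11.8054	6.33296	0.0234763	11.8056
3.18062	26.7871	20.5057	6.25627	0.0251516	20.5058
3.36079	40.8736	34.6715	6.17515	0.0269344	34.6716
3.55116	57.4032	51.285	6.08938	0.0288291	51.2852
3.60704	62.1619	56.0683	6.0642	0.0293868	56.0685
3.60776	511.723	505.63	6.06388	0.0293941	464.874
3.75232	638.859	632.829	5.99876	0.0308392	583.785
3.96487	752.215	746.279	5.90312	0.032967	691.543
4	756.515	750.594	5.88733	0.0333187	696.025
4.18946	730.93	725.092	5.8023	0.0352135	674.761
4.42677	641.043	635.309	5.6962	0.0375783	593.575
4.67753	537.807	532.183	5.58476	0.0400592	499.097
4.94249	456.823	451.312	5.46797	0.0426524	424.758
5	444.483	438.997	5.44277	0.0432107	413.465
5.22245	403.64	398.81	4.78469	0.0453525	376.604
5.51828	359.592	356.464	3.08003	0.0481523	337.679
5.83086	338.197	336.527	1.61824	0.0510432	319.744
6	323.871	322.464	1.35384	0.0525761	306.836
6.16115	308.239	306.807	1.37705	0.0540153	292.327
6.51015	271.05	269.368	1.62501	0.0570576	257.336
6.87892	232.732	230.663	2.00895	0.0601589	220.912
7.26858	197.553	195.108	2.38135	0.0633074	187.303
7.68031	167.391	164.713	2.61199	0.0664917	158.477
8	148.728	146.034	2.62479	0.0688653	140.727
8.11536	142.872	140.209	2.59271	0.0697011	135.186
8.57506	122.691	120.255	2.36305	0.0729257	116.178
9.06079	105.578	103.454	2.04839	0.0761567	100.135
9.57404	90.8279	89.0006	1.74787	0.0793865	86.2987
10	80.502	78.8436	1.57648	0.0819331	76.5523
10.1164	77.9317	76.3062	1.54289	0.0826088	74.1142
10.6894	66.7438	65.262	1.39607	0.0858184	63.4882
11.2949	57.1243	55.7674	1.26785	0.0890107	54.3335
11.9347	48.8621	47.6154	1.15444	0.0921817	46.4573
12.6108	41.7728	40.625	1.05246	0.0953274	39.6905
13.3251	35.6958	34.6383	0.958968	0.0984434	33.8848
14.0799	30.491	29.518	0.871469	0.101525	28.911
14.8775	26.0369	25.1445	0.787887	0.104565	24.6559
15	25.4314	24.5507	0.775671	0.105014	24.0776
15.7202	22.2219	21.4069	0.707417	0.107559	21.014
16.6107	18.9508	18.2084	0.631973	0.110496	17.893
17.5516	16.1536	15.4772	0.563096	0.113368	15.2244
18.5458	13.7673	13.1492	0.501907	0.116164	12.9469
19.5963	11.7356	11.1675	0.449159	0.118875	11.006
20	11.0634	10.5116	0.431871	0.119853	10.3631
20.7063	10.0056	9.48013	0.404017	0.121487	9.35151
21.8793	8.52613	8.03983	0.362307	0.123992	7.93783
23.1186	7.26358	6.81298	0.324216	0.126377	6.73249
24.4282	6.18882	5.77001	0.290174	0.128634	5.70689
25.8119	5.27581	4.88462	0.260433	0.130755	4.83554
27.274	4.50151	4.13369	0.235086	0.132733	4.09596
28.819	3.84569	3.49704	0.21409	0.134562	3.46851
30	3.43212	3.09488	0.201443	0.1358	3.07194
30.4514	3.29056	2.95714	0.197187	0.136239	2.93608
32.1763	2.81803	2.49808	0.18219	0.137762	2.48312
33.999	2.41571	2.10839	0.168189	0.13913	2.09844
35.9249	2.07395	1.77854	0.155065	0.140343	1.7727
37.9598	1.78416	1.50004	0.142722	0.141402	1.49759
40	1.55008	1.27617	0.131646	0.142268	1.27641
40.1101	1.53879	1.2654	0.131081	0.142309	1.26577
42.3821	1.33073	1.06788	0.119787	0.143066	1.0706
44.7828	1.15361	0.901129	0.108807	0.143675	0.905854
47.3196	1.00237	0.759839	0.0983929	0.144138	0.766282
50	0.87284	0.639661	0.0887215	0.144458	0.647599
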