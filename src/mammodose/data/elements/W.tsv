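# element W  Z=74  A=183.84  K_edge_keV=69.525
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	3680	3673.12	6.87677	0.00223072	3661.6
1.05665	3368.74	3361.87	6.86605	0.00245194	3351.9
1.1165	3092.45	3085.59	6.85432	0.00269146	3076.98
1.17974	2846.87	2840.03	6.84152	0.00295015	2832.64
1.24657	2628.36	2621.53	6.82757	0.00322887	2615.22
1.31718	2433.71	2426.9	6.81241	0.00352841	2421.54
1.39179	2260.16	2253.36	6.79597	0.0038495	2248.86
1.47063	2105.3	2098.52	6.77817	0.00419279	2094.78
1.5	2053.88	2047.1	6.77144	0.00432152	2043.61
1.55394	1967.03	1960.27	6.75896	0.0045589	1957.2
1.64196	1843.53	1836.78	6.73825	0.00494835	1834.31
1.73497	1733.19	1726.47	6.71601	0.00536161	1724.52
1.83325	1634.63	1627.93	6.69215	0.00579913	1626.45
1.93709	1546.63	1539.95	6.66664	0.00626129	1538.89
2	1500	1493.34	6.65107	0.00654081	1492.5
2.04682	1468.82	1462.17	6.63942	0.00674847	1461.47
2.16276	1404.46	1397.84	6.61045	0.00726102	1397.44
2.28527	1350.03	1343.45	6.57969	0.00779933	1343.28
2.41472	1301.25	1294.69	6.5471	0.00836381	1294.69
2.5515	1254.41	1247.89	6.51264	0.0089549	1247.89
2.69603	1206.33	1199.84	6.47628	0.00957314	1199.84
2.84875	1154.32	1147.88	6.438	0.0102191	1147.88
3	1100	1093.59	6.40027	0.0108516	1093.59
3.01012	1096.25	1089.84	6.39776	0.0108936	1089.84
3.18062	1032.1	1025.74	6.35553	0.0115974	1025.74
3.36079	964.175	957.851	6.3113	0.0123315	957.852
3.55116	894.365	888.087	6.26501	0.0130971	888.087
3.75232	824.348	818.117	6.21665	0.0138955	818.117
3.96487	755.529	749.349	6.16617	0.0147284	749.349
4	744.703	738.53	6.15788	0.0148651	738.53
4.18946	689.045	682.915	6.11352	0.0155974	682.916
4.42677	625.759	619.684	6.05865	0.0165046	619.684
4.67753	566.293	560.274	6.0015	0.0174519	560.274
4.94249	511.043	505.082	5.94201	0.0184417	505.082
5	500	494.052	5.92921	0.0186551	494.052
5.22245	458.401	452.501	5.8801	0.0194761	452.502
5.51828	406.032	400.196	5.81568	0.0205576	400.196
5.83086	356.079	350.309	5.74868	0.0216883	350.309
6	331.646	325.91	5.71286	0.0222952	325.911
6.16115	310.083	304.381	5.679	0.0228703	304.382
6.51015	268.924	263.293	5.60653	0.0241057	263.293
6.87892	232.955	227.399	5.5312	0.025396	227.399
7.26858	202.154	196.674	5.45291	0.0267428	196.675
7.68031	176.251	170.852	5.37158	0.0281472	170.852
8	160	154.661	5.30937	0.0292242	154.662
8.11536	154.805	149.489	5.28712	0.02961	149.489
8.57506	136.544	131.313	5.19949	0.0311316	131.314
9.06079	120.696	115.555	5.10864	0.0327123	115.555
9.57404	106.888	101.839	5.01453	0.0343519	101.84
10	97.2162	92.2427	4.93788	0.0356885	92.2433
10.1164	94.8104	89.8908	4.88354	0.0360498	89.8915
10.206	93.0201	88.1413	4.84246	0.0363269	88.142
10.208	220.014	215.137	4.84153	0.0363332	215.137
10.6894	226.773	222.103	4.63176	0.0378052	222.104
11.2949	235.127	230.695	4.39191	0.0396169	230.696
11.9347	243.788	239.583	4.16446	0.0414831	239.583
12.0988	245.984	241.832	4.11006	0.0419538	241.833
12.1012	269.911	265.76	4.10927	0.0419608	265.761
12.6108	236.068	232.075	3.94977	0.0434019	232.076
13.3251	198.236	194.443	3.74811	0.0453706	194.444
14.0799	167.418	163.811	3.55966	0.047386	163.812
14.8775	142.316	138.882	3.38452	0.0494443	138.883
15	139	135.591	3.35958	0.0497542	135.592
15.7202	121.897	118.625	3.2204	0.0515413	118.626
16.6107	105.12	102.002	3.06372	0.053672	102.004
17.5516	91.0358	88.065	2.91494	0.0558308	88.0668
18.5458	78.9677	76.1352	2.77446	0.0580116	76.1372
19.5963	68.4337	65.7309	2.6426	0.060208	65.733
20	64.8526	62.1955	2.59603	0.0610234	62.1977
20.7063	59.1538	56.5728	2.51849	0.0624131	56.5752
21.8793	51.1176	48.6546	2.39832	0.0646196	48.6571
23.1186	44.1731	41.8245	2.28176	0.0668201	41.8273
24.4282	38.1721	35.9342	2.16886	0.0690072	35.9372
25.8119	32.9863	30.8555	2.05964	0.0711733	30.8587
27.274	28.505	26.4776	1.95414	0.0733109	26.4811
28.819	24.6325	22.7047	1.85235	0.0754124	22.7085
30	22.1455	20.2881	1.78051	0.0769173	20.2921
30.4514	21.2861	19.4544	1.75429	0.0774705	19.4584
32.1763	18.3943	16.655	1.65982	0.079478	16.6594
33.999	15.8954	14.2455	1.56852	0.0814277	14.2502
35.9249	13.736	12.1726	1.48002	0.0833129	12.1777
37.9598	11.8699	10.3908	1.39402	0.0851269	10.3962
40	10.3323	8.93111	1.31442	0.0867785	8.93692
40.1101	10.2573	8.86019	1.3103	0.0868632	8.86601
42.3821	8.86386	7.54623	1.22912	0.0885157	7.55245
44.7828	7.65968	6.41875	1.15085	0.0900786	6.42538
47.3196	6.61909	5.45193	1.07561	0.0915465	5.45899
50	5.71987	4.62348	1.00348	0.0929143	4.63098
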