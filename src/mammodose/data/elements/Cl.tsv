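# element Cl  Z=17  A=35.45  K_edge_keV=2.8224
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	92.522	86.0895	6.42956	0.00297994	86.0895
1.05665	43.9644	37.5431	6.41792	0.00331573	37.5432
1.1165	24.7799	18.3712	6.40499	0.003688	18.3712
1.17974	16.4366	10.0418	6.39063	0.00410038	10.0418
1.24657	12.4815	6.10227	6.37471	0.00455683	6.10228
1.31718	10.4641	4.10198	6.35707	0.00506156	4.10199
1.39179	9.37722	3.03407	6.33753	0.0056191	3.03409
1.47063	8.77783	2.45569	6.31591	0.00623427	2.4557
1.5	8.63823	2.32415	6.3076	0.00647005	2.32417
1.55394	8.46112	2.1622	6.29201	0.00691217	2.16222
1.64196	8.33165	2.05837	6.26562	0.00765816	2.0584
1.73497	8.35002	2.10502	6.23652	0.00847779	2.10505
1.83325	8.51076	2.29692	6.20447	0.00937685	2.29695
1.93709	8.83462	2.65503	6.16922	0.0103612	2.65507
2	9.11457	2.95639	6.14721	0.0109736	2.95643
2.04682	9.36864	3.22668	6.13053	0.0114367	3.22672
2.16276	10.1909	4.09021	6.08811	0.0126093	4.09027
2.28527	11.4201	5.36447	6.04172	0.0138846	5.36453
2.41472	13.2245	7.2181	5.99108	0.015268	7.21817
2.5515	15.8284	9.87566	5.93593	0.0167645	9.87575
2.69603	19.505	13.6106	5.87601	0.0183784	13.6107
2.82212	23.5677	17.7254	5.82252	0.0198087	17.7255
2.82268	174.985	169.143	5.82228	0.0198152	160.003
2.84875	184.148	178.317	5.81109	0.0201131	168.77
3	243.318	237.551	5.74539	0.0218541	225.474
3.01012	247.637	241.874	5.74095	0.0219712	229.618
3.18062	325.602	319.913	5.66541	0.0239541	304.571
3.36079	412.641	407.031	5.58433	0.0260618	388.558
3.55116	552.193	546.667	5.49759	0.028293	523.188
3.75232	723.511	718.075	5.40515	0.0306447	688.886
3.96487	823.359	818.019	5.30702	0.0331123	786.55
4	824.592	819.268	5.29078	0.0335178	788.028
4.18946	782.766	777.527	5.20328	0.0356898	749.22
4.42677	676.793	671.661	5.09406	0.0383695	648.519
4.67753	562.071	557.051	4.9796	0.0411425	538.887
4.94249	472.925	468.021	4.86017	0.0439991	453.578
5	459.128	454.249	4.83449	0.0446085	440.392
5.22245	415.488	411.202	4.23892	0.0469286	399.193
5.51828	369.058	366.288	2.71954	0.0499202	356.165
5.83086	312.249	310.772	1.42397	0.0529631	302.643
6	285.766	284.522	1.18921	0.0545591	277.29
6.16115	262.6	261.336	1.20761	0.0560471	254.867
6.51015	218.88	217.401	1.42028	0.059163	212.308
6.87892	181.543	179.731	1.7501	0.0623025	175.746
7.26858	150.633	148.499	2.06797	0.0654588	145.384
7.68031	125.754	123.423	2.26143	0.0686268	120.973
8	110.846	108.508	2.26767	0.0709765	106.44
8.11536	106.223	103.913	2.23833	0.0718022	101.961
8.57506	90.4962	88.3866	2.0346	0.0749825	86.8157
9.06079	77.3882	75.5508	1.75924	0.0781655	74.2803
9.57404	66.2469	64.6679	1.49759	0.0813498	63.6392
10	58.5336	57.1014	1.34834	0.0838654	56.232
10.1164	56.6268	55.2233	1.31901	0.0845338	54.3923
10.6894	48.3554	47.0768	1.19095	0.0877157	46.4068
11.2949	41.2799	40.1097	1.07935	0.0908926	39.57
11.9347	35.2294	34.1545	0.980817	0.0940604	33.7201
12.6108	30.057	29.0675	0.892359	0.0972136	28.7182
13.3251	25.6366	24.7249	0.811411	0.100345	24.4443
14.0799	21.8599	21.0206	0.735805	0.103446	20.7956
14.8775	18.6339	17.8636	0.663759	0.106505	17.6834
15	18.1956	17.4354	0.653245	0.106957	17.2611
15.7202	15.8749	15.1708	0.594583	0.109512	15.0267
16.6107	13.514	12.8716	0.529883	0.112454	12.7569
17.5516	11.5002	10.914	0.470936	0.115317	10.8228
18.5458	9.78748	9.25073	0.418661	0.118088	9.17862
19.5963	8.33427	7.83986	0.373652	0.120755	7.78312
20	7.85476	7.37414	0.358908	0.121713	7.32229
20.7063	7.10088	6.64239	0.335179	0.123306	6.59805
21.8793	6.04702	5.62154	0.299747	0.12573	5.58728
23.1186	5.14885	4.75334	0.267497	0.128019	4.72725
24.4282	4.38569	4.01676	0.238764	0.130166	3.99731
25.8119	3.73891	3.39302	0.213727	0.132164	3.37898
27.274	3.19196	2.86552	0.192434	0.134011	2.8559
28.819	2.73026	2.41973	0.174818	0.135705	2.41374
30	2.44005	2.139	0.164208	0.136842	2.13525
30.4514	2.34087	2.04299	0.160639	0.137244	2.03999
32.1763	2.00979	1.72307	0.148091	0.138629	1.72258
33.999	1.72803	1.45175	0.136421	0.139861	1.45337
35.9249	1.48892	1.22246	0.125522	0.140942	1.22586
37.9598	1.28648	1.0293	0.115309	0.141873	1.03423
40	1.12329	0.874497	0.106174	0.142621	0.880701
40.1101	1.11543	0.867065	0.105709	0.142657	0.873332
42.3821	0.970505	0.730779	0.0964306	0.143295	0.738218
44.7828	0.84703	0.615797	0.0874428	0.14379	0.624285
47.3196	0.741511	0.518423	0.0789441	0.144144	0.527865
50	0.651067	0.435637	0.0710715	0.144359	0.445959
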