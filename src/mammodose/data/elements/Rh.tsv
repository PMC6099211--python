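# element Rh  Z=45  A=102.906  K_edge_keV=23.2199
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	9860.25	9855.72	4.52156	0.00321078	9810.94
1.05665	8544.21	8539.69	4.51218	0.00353268	8501.49
1.1165	7403.82	7399.32	4.50191	0.00388195	7366.81
1.17974	6415.64	6411.15	4.49068	0.00426009	6383.57
1.24657	5559.36	5554.87	4.47845	0.00466857	5531.56
1.31718	4817.36	4812.89	4.46513	0.00510881	4793.27
1.39179	4174.39	4169.93	4.45066	0.00558223	4153.52
1.47063	3617.24	3612.8	4.43498	0.00609018	3599.15
1.5	3435.98	3431.54	4.42904	0.00628113	3418.8
1.55394	3134.45	3130.03	4.41801	0.00663398	3118.78
1.64196	2716.1	2711.69	4.39971	0.00721494	2702.52
1.73497	2353.58	2349.2	4.37999	0.00783436	2341.82
1.83325	2039.45	2035.09	4.35881	0.00849354	2029.26
1.93709	1767.25	1762.91	4.33609	0.00919383	1758.41
2	1626.33	1622	4.32219	0.00961942	1618.2
2.04682	1531.38	1527.06	4.31179	0.00993662	1523.72
2.16276	1326.99	1322.69	4.28585	0.0107233	1320.35
2.28527	1149.88	1145.61	4.25821	0.0115555	1144.13
2.41472	996.403	992.161	4.22882	0.0124347	991.421
2.5515	863.414	859.203	4.19763	0.0133625	859.097
2.69603	748.175	743.996	4.16458	0.0143404	743.996
2.84875	648.317	644.172	4.12963	0.0153701	644.172
3	566.725	562.614	4.09503	0.0163853	562.614
3.01012	561.787	557.678	4.09272	0.016453	557.678
3.18062	486.806	482.735	4.05382	0.0175902	482.735
3.36079	421.833	417.801	4.01288	0.0187828	417.801
3.41166	405.674	401.654	4.00136	0.0191177	401.654
3.41234	1824.56	1820.54	4.0012	0.0191222	1815.43
3.55116	1635.06	1631.07	3.96986	0.0200316	1626.88
3.75232	1405.17	1401.22	3.92472	0.0213368	1398.14
3.96487	1207.6	1203.7	3.87745	0.0226986	1201.56
4	1178.65	1174.76	3.86969	0.0229219	1172.76
4.18946	1037.81	1033.96	3.82803	0.0241167	1032.62
4.42677	891.891	888.089	3.77645	0.0255904	887.432
4.67753	766.49	762.74	3.72271	0.0271188	762.658
4.94249	658.721	655.025	3.66684	0.028701	655.026
5	638.093	634.409	3.65484	0.0290399	634.41
5.22245	566.104	562.465	3.60886	0.0303356	562.465
5.51828	486.509	482.928	3.54881	0.0320217	482.929
5.83086	418.106	414.585	3.48675	0.0337582	414.585
6	386.488	382.999	3.45377	0.0346789	383
6.16115	359.319	355.861	3.42274	0.0355441	355.862
6.51015	308.799	305.405	3.35684	0.0373789	305.405
6.87892	265.381	262.053	3.28914	0.0392618	262.053
7.26858	228.068	224.808	3.21971	0.0411927	224.808
7.68031	196.002	192.81	3.14864	0.0431713	192.811
8	175.208	172.068	3.09502	0.0446664	172.069
8.11536	168.444	165.323	3.076	0.0451974	165.323
8.57506	144.76	141.711	3.00189	0.0472707	141.712
9.06079	124.407	121.431	2.92639	0.0493905	121.432
9.57404	106.915	104.014	2.84958	0.0515561	104.015
10	94.8531	92.0118	2.78803	0.0532984	92.0128
10.1164	91.8828	89.0764	2.7526	0.053766	89.0774
10.6894	78.964	76.3189	2.58911	0.0560186	76.32
11.2949	67.8616	65.3688	2.43441	0.0583114	65.3701
11.9347	58.3202	55.9709	2.28863	0.0606416	55.9722
12.6108	50.1203	47.9055	2.15182	0.0630055	47.9069
13.3251	43.0733	40.9839	2.02399	0.0653993	40.9855
14.0799	37.0172	35.0443	1.90506	0.0678182	35.046
14.8775	31.8125	29.9473	1.79492	0.0702571	29.9493
15	31.1029	29.253	1.77926	0.0706215	29.255
15.7202	27.3396	25.5747	1.69219	0.0727103	25.5768
16.6107	23.4957	21.8256	1.59487	0.0751716	21.8279
17.5516	20.1921	18.6114	1.5031	0.0776342	18.6139
18.5458	17.3531	15.856	1.41699	0.080091	15.8587
19.5963	14.9132	13.4941	1.33659	0.0825342	13.497
20	14.1	12.7083	1.30828	0.0834333	12.7113
20.7063	12.8164	11.4701	1.26134	0.0849556	11.4733
21.8793	11.0144	9.73782	1.18926	0.0873467	9.74124
23.1186	9.46578	8.25595	1.12014	0.0896987	8.25964
23.2176	9.35524	8.15046	1.1149	0.0898791	8.15418
23.2222	55.1659	53.9613	1.11465	0.0898876	23.4369
24.4282	48.1177	46.9718	1.05395	0.0920026	21.7138
25.8119	41.4664	40.3815	0.99067	0.0942496	19.8324
27.274	35.7345	34.7078	0.930267	0.0964308	17.9938
28.819	30.7949	29.8237	0.8727	0.0985378	16.2328
30	27.6301	26.6976	0.832499	0.100022	15.0113
30.4514	26.5381	25.6196	0.817925	0.100563	14.5718
32.1763	22.8697	22.0014	0.76583	0.102498	13.0238
33.999	19.7085	18.8879	0.716179	0.104336	11.5954
35.9249	16.9842	16.2093	0.668758	0.106072	10.288
37.9598	14.6364	13.9053	0.623396	0.1077	9.09963
40	12.7072	12.0159	0.582078	0.109142	8.07668
40.1101	12.6132	11.9241	0.579955	0.109214	8.02574
42.3821	10.8697	10.2206	0.538508	0.110612	7.06014
44.7828	9.36718	8.75612	0.499172	0.11189	6.19561
47.3196	8.07236	7.49737	0.461939	0.113044	5.42452
50	6.95651	6.41565	0.426788	0.114073	4.73911
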