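# element Cu  Z=29  A=63.546  K_edge_keV=8.9789
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	10570	10567	3.03268	0.0038224	10517.2
1.05665	9477.25	9474.22	3.02549	0.00420635	9429.86
1.1165	8469.34	8466.32	3.01762	0.00462289	8427
1.17974	7545.07	7542.06	3.00902	0.00507372	7507.35
1.24657	6702.07	6699.07	2.99964	0.00556049	6668.56
1.31718	5937.09	5934.09	2.98944	0.00608478	5907.4
1.39179	5246.16	5243.17	2.97836	0.00664807	5219.93
1.47063	4624.87	4621.9	2.96636	0.00725177	4601.75
1.5	4418	4415.03	2.96182	0.00747853	4395.91
1.55394	4065.29	4062.32	2.95338	0.00789723	4044.96
1.64196	3555.63	3552.69	2.93939	0.00858571	3537.86
1.73497	3097.92	3094.99	2.92435	0.0093185	3082.43
1.83325	2692.54	2689.62	2.90819	0.0100969	2679.07
1.93709	2337.77	2334.87	2.8909	0.0109222	2326.09
2	2154	2151.11	2.88034	0.0114231	2143.23
2.04682	2029.98	2027.09	2.87243	0.011796	2019.83
2.16276	1760.81	1757.94	2.85275	0.0127201	1752
2.28527	1525.37	1522.52	2.83182	0.0136963	1517.74
2.41472	1320	1317.18	2.8096	0.0147271	1313.4
2.5515	1141.33	1138.52	2.78607	0.0158151	1135.62
2.69603	986.225	983.447	2.76118	0.0169633	981.294
2.84875	851.864	849.111	2.7349	0.0181752	847.604
3	742.3	739.572	2.70892	0.0193742	738.588
3.01012	735.677	732.951	2.70718	0.0194544	731.999
3.18062	634.78	632.081	2.67799	0.0208048	631.606
3.36079	547.123	544.454	2.64726	0.0222305	544.388
3.55116	471.357	468.718	2.61496	0.0237356	468.718
3.75232	406.157	403.551	2.58103	0.0253236	403.551
3.96487	350.264	347.692	2.5454	0.0269982	347.692
4	342.1	339.533	2.53954	0.0272745	339.533
4.18946	302.308	299.771	2.50804	0.028762	299.771
4.42677	260.983	258.484	2.46888	0.0306173	258.484
4.67753	225.491	223.03	2.42789	0.0325652	223.031
4.94249	195.098	192.678	2.38504	0.0346058	192.678
5	189.3	186.889	2.3758	0.035046	186.889
5.22245	169.312	166.935	2.3403	0.0367382	166.935
5.51828	147.358	145.025	2.29367	0.0389601	145.025
5.83086	128.004	125.717	2.24516	0.0412682	125.718
6	118.7	116.438	2.21926	0.0424985	116.439
6.16115	110.471	108.233	2.19482	0.0436579	108.233
6.51015	94.7266	92.5378	2.14269	0.0461235	92.5383
6.87892	80.911	78.7734	2.08887	0.0486585	78.7741
7.26858	69.0151	66.9304	2.03346	0.0512558	66.9311
7.68031	58.9348	56.9043	1.97658	0.0539076	56.905
8	52.55	50.5605	1.93363	0.0559009	50.5613
8.11536	50.5047	48.5297	1.9184	0.0566061	48.5305
8.57506	43.4098	41.4914	1.85907	0.0593434	41.4923
8.978	38.3104	36.4399	1.80887	0.0616486	36.4409
8.9798	278.336	276.466	1.80865	0.0616587	196.187
9.06079	272.638	270.777	1.79877	0.0621116	192.854
9.57404	239.799	237.997	1.73769	0.0649034	173.178
10	215.9	214.144	1.68902	0.067121	158.306
10.1164	209.808	208.076	1.66457	0.0677117	154.445
10.6894	182.614	180.991	1.55207	0.0705298	136.842
11.2949	158.377	156.858	1.44613	0.0733515	120.647
11.9347	136.975	135.552	1.34682	0.0761705	105.938
12.6108	118.227	116.894	1.25416	0.078981	92.7256
13.3251	101.92	100.67	1.16807	0.0817772	80.9724
14.0799	87.8225	86.6495	1.08845	0.084553	70.6046
14.8775	75.7001	74.5977	1.01513	0.0873025	61.5255
15	74.05	72.9576	1.00474	0.0877092	60.2774
15.7202	65.262	64.2247	0.947245	0.0900192	53.5743
16.6107	56.2054	55.2291	0.883581	0.0926969	46.5621
17.5516	48.3634	47.4439	0.824144	0.0953289	40.3985
18.5458	41.5868	40.72	0.768909	0.0979087	34.9981
19.5963	35.7415	34.9233	0.71781	0.10043	30.2799
20	33.79	32.9887	0.699928	0.101346	28.6914
20.7063	30.7048	29.9315	0.67046	0.102885	26.1661
21.8793	26.3613	25.6303	0.625715	0.105269	22.5798
23.1186	22.6196	21.9286	0.583408	0.107575	19.4598
24.4282	19.4003	18.7471	0.543465	0.109796	16.7507
25.8119	16.6335	16.0157	0.505808	0.111927	14.4029
27.274	14.2578	13.6735	0.470356	0.113962	12.3717
28.819	12.2198	11.6669	0.437028	0.115895	10.6171
30	10.92	10.3887	0.414023	0.117237	9.49188
30.4514	10.4724	9.94898	0.405737	0.11772	9.10327
32.1763	8.97032	8.47452	0.376372	0.119432	7.79437
33.999	7.68036	7.21058	0.348758	0.121025	6.6646
35.9249	6.57534	6.1301	0.322743	0.122495	5.69263
37.9598	5.63076	5.20873	0.298199	0.123837	4.85885
40	4.862	4.46087	0.276143	0.12499	4.17843
40.1101	4.82478	4.42471	0.275018	0.125047	4.14545
42.3821	4.13662	3.75731	0.253196	0.126122	3.535
44.7828	3.54802	3.18821	0.232752	0.127062	3.01192
47.3196	3.0443	2.70279	0.213643	0.127863	2.56372
50	2.613	2.28865	0.195825	0.128526	2.17967
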