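# element Na  Z=11  A=22.99  K_edge_keV=1.0721
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	710.786	707.628	3.15199	0.00546705	707.232
1.05665	644.881	641.738	3.13659	0.00600619	641.656
1.07199	628.037	624.9	3.13075	0.00615446	624.896
1.07221	7430.74	7427.6	3.13067	0.00615654	7351.24
1.1165	6896.35	6893.23	3.11046	0.00658924	6825.17
1.17974	6206.99	6203.91	3.07451	0.00721818	6145.94
1.24657	5566.48	5563.44	3.02967	0.00789493	5514.25
1.31718	4974.81	4971.83	2.97687	0.00862126	4930.22
1.39179	4431.26	4428.33	2.91704	0.00939882	4393.26
1.47063	3934.48	3931.62	2.85113	0.0102292	3902.15
1.5	3767.29	3764.45	2.82617	0.0105403	3736.79
1.55394	3482.57	3479.8	2.75932	0.0111138	3455.11
1.64196	3073.06	3070.46	2.58768	0.0120542	3049.85
1.73497	2703.75	2701.37	2.37111	0.013052	2684.2
1.83325	2372.06	2369.89	2.15103	0.0141088	2355.64
1.93709	2074.86	2072.87	1.96769	0.0152266	2061.08
2	1917.11	1915.2	1.8936	0.0159038	1904.64
2.04682	1809.09	1807.22	1.8521	0.0164077	1797.49
2.16276	1571.56	1569.78	1.7617	0.017655	1561.77
2.28527	1360.85	1359.15	1.68142	0.0189718	1352.59
2.41472	1175.43	1173.8	1.60919	0.0203623	1168.44
2.5515	1013.4	1011.83	1.54301	0.0218312	1007.46
2.69603	872.684	871.18	1.48091	0.0233842	867.618
2.84875	751.136	749.69	1.421	0.0250275	746.789
3	652.567	651.176	1.36514	0.0266588	648.783
3.01012	646.631	645.243	1.36149	0.026768	642.88
3.18062	556.373	555.042	1.30299	0.0286134	553.118
3.36079	478.113	476.835	1.24697	0.0305713	475.272
3.55116	362.463	361.237	1.19356	0.0326498	360.115
3.75232	283.362	282.184	1.14284	0.0348568	281.355
3.96487	232.34	231.208	1.09454	0.0371997	230.566
4	225.849	224.724	1.08685	0.0375879	224.105
4.18946	196.285	195.2	1.04504	0.0396853	194.687
4.42677	167.813	166.776	0.994647	0.0423192	166.361
4.67753	144.071	143.077	0.949559	0.0451056	142.74
4.94249	123.317	122.354	0.915539	0.0480467	122.081
5	119.223	118.265	0.910294	0.0486839	118.004
5.22245	104.698	103.749	0.897068	0.0511426	103.531
5.51828	88.5347	87.5925	0.887731	0.054391	87.4181
5.83086	74.8977	73.965	0.874904	0.0577865	73.8258
6	68.7798	67.8571	0.863076	0.059604	67.7331
6.16115	63.6384	62.7304	0.846677	0.0613208	62.6189
6.51015	54.2922	53.4302	0.797058	0.0649825	53.3405
6.87892	46.4248	45.6199	0.736089	0.0687568	45.5477
7.26858	39.7345	38.9769	0.684956	0.0726262	38.9188
7.68031	33.9652	33.2581	0.630506	0.0765701	33.2115
8	30.1913	29.5106	0.601128	0.079524	29.4712
8.11536	28.9554	28.2822	0.592605	0.0805659	28.2451
8.57506	24.6188	23.9734	0.560852	0.084589	23.9439
9.06079	20.9013	20.2821	0.530517	0.0886139	20.259
9.57404	17.7377	17.1437	0.501328	0.0926149	17.1257
10	15.5872	15.0126	0.478928	0.0957423	14.9978
10.1164	15.0626	14.4948	0.47126	0.0965668	14.4808
10.6894	12.7925	12.2562	0.435884	0.100446	12.2455
11.2949	10.8613	10.3546	0.402483	0.10423	10.3467
11.9347	9.22303	8.74255	0.372585	0.107901	8.73687
12.6108	7.83519	7.37817	0.345581	0.111442	7.37433
13.3251	6.66006	6.22496	0.32026	0.11484	6.22264
14.0799	5.66596	5.25123	0.296645	0.118087	5.25019
14.8775	4.82388	4.42964	0.273068	0.121176	4.42967
15	4.70994	4.31884	0.269471	0.121622	4.31902
15.7202	4.10724	3.73334	0.249793	0.124104	3.7343
16.6107	3.49623	3.14091	0.228453	0.126868	3.14267
17.5516	2.97901	2.64061	0.208934	0.12947	2.64309
18.5458	2.54395	2.22091	0.191126	0.131911	2.22402
19.5963	2.17996	1.87085	0.174924	0.134194	1.87454
20	2.06121	1.7569	0.169313	0.134999	1.7608
20.7063	1.87479	1.57831	0.160167	0.136321	1.58254
21.8793	1.61329	1.32842	0.146572	0.138294	1.33317
23.1186	1.3899	1.11574	0.134044	0.140117	1.12098
24.4282	1.2002	0.935759	0.122657	0.141789	0.941473
25.8119	1.03982	0.784251	0.112259	0.143314	0.790435
27.274	0.904714	0.657362	0.102662	0.14469	0.664013
28.819	0.791368	0.551643	0.0938056	0.145919	0.558759
30	0.720677	0.486168	0.0877866	0.146722	0.493625
30.4514	0.696589	0.463949	0.0856387	0.147001	0.471533
32.1763	0.615797	0.389736	0.0781255	0.147935	0.397792
33.999	0.546605	0.32667	0.0712125	0.148723	0.335206
35.9249	0.487653	0.273444	0.0648452	0.149364	0.282466
37.9598	0.437708	0.228872	0.0589761	0.149859	0.238388
40	0.397602	0.193581	0.0538235	0.150197	0.203573
40.1101	0.395676	0.191902	0.0535639	0.150211	0.201919
42.3821	0.35997	0.160966	0.0485828	0.150421	0.171493
44.7828	0.329293	0.134787	0.0440134	0.150492	0.145832
47.3196	0.303022	0.112764	0.0398302	0.150428	0.124335
50	0.280638	0.0943976	0.0360077	0.150233	0.106502
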