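# element O  Z=8  A=15.999  K_edge_keV=0.5431
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	4590.91	4587.76	3.13788	0.00417438	4567.95
1.05665	3972.44	3969.31	3.12425	0.00464669	3952.57
1.1165	3433.85	3430.74	3.09854	0.00517076	3416.68
1.17974	2965.44	2962.38	3.06176	0.00575187	2950.62
1.24657	2558.59	2555.57	3.01492	0.00639574	2545.8
1.31718	2205.64	2202.68	2.95902	0.00710856	2194.61
1.39179	1899.81	1896.91	2.89508	0.00789697	1890.31
1.47063	1635.1	1632.27	2.8241	0.00876811	1626.92
1.5	1549.1	1546.29	2.79711	0.00910233	1541.36
1.55394	1406.06	1403.32	2.72325	0.00972955	1399.03
1.64196	1207.62	1205.08	2.53034	0.0107893	1201.58
1.73497	1036.05	1033.75	2.28538	0.0119559	1030.87
1.83325	888.013	885.963	2.03598	0.0132381	883.573
1.93709	760.532	758.689	1.82857	0.0146449	756.729
2	694.944	693.184	1.74529	0.0155217	691.47
2.04682	650.931	649.215	1.69893	0.0161857	647.676
2.16276	556.73	555.114	1.59804	0.0178697	553.946
2.28527	475.826	474.298	1.50856	0.0197061	473.447
2.41472	406.409	404.96	1.42811	0.0217039	404.377
2.5515	346.903	345.524	1.35436	0.0238715	345.168
2.69603	295.935	294.624	1.28508	0.0262163	294.449
2.84875	252.318	251.071	1.21811	0.0287448	250.93
3	217.134	215.947	1.15554	0.0312906	215.832
3.01012	215.019	213.836	1.15145	0.0314621	213.723
3.18062	183.096	181.976	1.08588	0.0343713	181.885
3.36079	155.78	154.72	1.02312	0.0374734	154.646
3.55116	132.45	131.446	0.963386	0.0407671	131.387
3.75232	112.556	111.605	0.906847	0.044248	111.558
3.96487	95.6189	94.7173	0.853665	0.0479086	94.6795
4	93.1527	92.2588	0.845471	0.0485107	92.2223
4.18946	81.2412	80.3883	0.801109	0.0517383	80.3581
4.42677	69.0305	68.2267	0.748075	0.055723	68.2025
4.67753	58.59	57.8292	0.700962	0.0598452	57.81
4.94249	49.614	48.8845	0.665457	0.0640843	48.8693
5	47.8921	47.1672	0.659939	0.0649871	47.1527
5.22245	41.8274	41.1133	0.645695	0.0684171	41.1014
5.51828	35.1177	34.4099	0.635001	0.0728179	34.4007
5.83086	29.5159	28.8176	0.621041	0.0772598	28.8105
6	27.0293	26.3408	0.608972	0.0795719	26.3346
6.16115	24.9518	24.2773	0.592783	0.0817149	24.272
6.51015	21.1947	20.5632	0.545316	0.0861555	20.5592
6.87892	18.052	17.4727	0.488743	0.0905552	17.4698
7.26858	15.3903	14.8623	0.433043	0.0948891	14.8604
7.68031	13.1112	12.6257	0.386386	0.0991352	12.6245
8	11.6273	11.1636	0.361507	0.10221	11.1629
8.11536	11.1425	10.6846	0.3546	0.103275	10.6841
8.57506	9.44461	9.00778	0.329545	0.107292	9.00783
9.06079	7.99705	7.57928	0.306601	0.111175	7.57984
9.57404	6.77512	6.3748	0.285403	0.114917	6.3758
10	5.95188	5.56443	0.269681	0.11777	5.56575
10.1164	5.75178	5.36764	0.265629	0.118512	5.36904
10.6894	4.88606	4.51719	0.246908	0.121959	4.51896
11.2949	4.15079	3.79636	0.22918	0.125256	3.79846
11.9347	3.52851	3.18762	0.212485	0.128407	3.19004
12.6108	3.00338	2.67513	0.196838	0.131414	2.67787
13.3251	2.56131	2.2448	0.182238	0.134281	2.24784
14.0799	2.18987	1.8842	0.168668	0.137009	1.88754
14.8775	1.87824	1.58254	0.156098	0.139601	1.58619
15	1.83637	1.54208	0.154309	0.139976	1.54578
15.7202	1.6144	1.32793	0.144412	0.14206	1.33189
16.6107	1.38872	1.11089	0.13344	0.144385	1.11517
17.5516	1.19806	0.92834	0.123147	0.146576	0.932937
18.5458	1.03886	0.776731	0.1135	0.148631	0.781661
19.5963	0.907396	0.652379	0.104469	0.150548	0.657652
20	0.865051	0.612552	0.101277	0.151223	0.617954
20.7063	0.798622	0.550264	0.0960323	0.152325	0.555892
21.8793	0.704655	0.46251	0.0881864	0.153959	0.468503
23.1186	0.623648	0.387309	0.0808935	0.155445	0.393682
24.4282	0.554286	0.323387	0.0741167	0.156782	0.330151
25.8119	0.495295	0.269505	0.0678228	0.157967	0.276674
27.274	0.445485	0.224505	0.0619816	0.158999	0.232092
28.819	0.403782	0.18734	0.0565654	0.159877	0.195358
30	0.377944	0.164654	0.0528703	0.16042	0.172993
30.4514	0.369176	0.157026	0.0515492	0.160601	0.165487
32.1763	0.339691	0.131594	0.0469247	0.161173	0.14051
33.999	0.314273	0.110007	0.0426716	0.161595	0.119391
35.9249	0.292421	0.0917871	0.0387647	0.16187	0.101651
37.9598	0.273716	0.0765349	0.0351797	0.162001	0.08689
40	0.258535	0.0644867	0.0320507	0.161998	0.0753188
40.1101	0.257802	0.0639144	0.0318936	0.161994	0.0747718
42.3821	0.244061	0.0533202	0.028888	0.161853	0.0646904
44.7828	0.232093	0.0443661	0.0261445	0.161582	0.0562592
47.3196	0.22183	0.0370002	0.0236428	0.161187	0.0494257
50	0.213217	0.0311797	0.0213638	0.160673	0.0441463
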