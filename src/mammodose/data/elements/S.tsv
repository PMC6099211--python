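# element S  Z=16  A=32.06  K_edge_keV=2.472
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	210.774	204.487	6.28289	0.00355046	204.487
1.05665	123.009	116.735	6.26988	0.00394768	116.735
1.1165	77.3747	71.1149	6.25544	0.00438738	71.1149
1.17974	52.4307	46.1864	6.23944	0.00487366	46.1864
1.24657	38.1641	31.937	6.22172	0.00541088	31.937
1.31718	29.6825	23.4744	6.2021	0.00600371	23.4744
1.39179	24.4919	18.3048	6.18042	0.00665708	18.3048
1.47063	21.2719	15.1081	6.15646	0.00737618	15.1081
1.5	20.447	14.2921	6.14728	0.0076513	14.2921
1.55394	19.3018	13.1636	6.13004	0.00816643	13.1636
1.64196	18.1812	12.0712	6.10094	0.0090334	12.0713
1.73497	17.6897	11.6108	6.06892	0.00998282	11.6108
1.83325	17.714	11.6693	6.03374	0.0110205	11.6693
1.93709	18.2082	12.2009	5.99518	0.012152	12.2009
2	18.7093	12.7253	5.97116	0.0128536	12.7254
2.04682	19.1735	13.2071	5.95298	0.0133831	13.2072
2.16276	20.6427	14.7211	5.90688	0.014719	14.7212
2.28527	22.6794	16.8066	5.85665	0.0161645	16.8067
2.41472	25.3603	19.5405	5.80204	0.0177241	19.5406
2.47175	26.7327	20.9368	5.77753	0.0184202	20.9369
2.47225	211.716	205.92	5.77732	0.0184263	197.026
2.5515	231.763	226.001	5.74283	0.0194014	216.542
2.69603	272.969	267.269	5.67882	0.0211989	256.683
2.84875	320.915	315.282	5.6098	0.0231183	303.463
3	370.176	364.611	5.54033	0.0250318	351.632
3.01012	373.447	367.886	5.53565	0.02516	354.834
3.18062	425.711	420.228	5.45624	0.027323	406.119
3.36079	469.519	464.118	5.37151	0.0296049	449.371
3.55116	580.41	575.097	5.28145	0.0320018	557.802
3.75232	707.554	702.333	5.1861	0.0345084	682.345
3.96487	763.525	758.402	5.08556	0.0371181	737.976
4	760.852	755.745	5.06899	0.0375449	735.569
4.18946	711.707	706.687	4.98	0.0398229	688.674
4.42677	614.598	609.685	4.86965	0.0426142	594.978
4.67753	513.801	509.001	4.75481	0.0454827	497.381
4.94249	434.013	429.329	4.63581	0.0484188	420.053
5	421.146	416.487	4.61033	0.049043	407.592
5.22245	379.445	375.354	4.03928	0.0514132	367.679
5.51828	334.419	331.776	2.58916	0.0544572	325.355
5.83086	277.99	276.578	1.35465	0.0575428	271.513
6	252.712	251.522	1.13091	0.0591583	247.046
6.16115	231.23	230.021	1.14807	0.0606634	226.035
6.51015	191.862	190.449	1.34951	0.0638135	187.326
6.87892	159.079	157.35	1.66217	0.0669893	154.908
7.26858	132.236	130.203	1.96342	0.0701881	128.291
7.68031	110.624	108.404	2.14658	0.0734081	106.898
8	97.5594	95.3314	2.15222	0.0758047	94.06
8.11536	93.4773	91.2763	2.12429	0.0766487	90.0764
8.57506	79.5366	77.526	1.9307	0.0799092	76.5618
9.06079	67.8754	66.123	1.66924	0.0831891	65.3451
9.57404	57.9731	56.4657	1.42083	0.086487	55.8375
10	51.1509	49.7827	1.27911	0.0891037	49.2527
10.1164	49.4722	48.1311	1.25124	0.0898006	47.6248
10.6894	42.1968	40.9741	1.12955	0.0931263	40.5666
11.2949	35.983	34.8631	1.02343	0.0964584	34.5355
11.9347	30.6775	29.648	0.929654	0.0997896	29.385
12.6108	26.1487	25.2002	0.845399	0.10311	24.9892
13.3251	22.2838	21.4092	0.768241	0.10641	21.2402
14.0799	18.9858	18.18	0.696144	0.109674	18.045
14.8775	16.1718	15.4315	0.627439	0.11289	15.3238
15	15.7897	15.059	0.617414	0.113364	14.9549
15.7202	13.7671	13.0895	0.561497	0.116043	13.0039
16.6107	11.7109	11.092	0.499857	0.119116	11.0243
17.5516	9.95916	9.39333	0.443734	0.122095	9.34008
18.5458	8.47147	7.95251	0.393994	0.124967	7.91092
19.5963	7.21157	6.73266	0.351193	0.127716	6.70049
20	6.79645	6.33058	0.337175	0.128701	6.30142
20.7063	6.14405	5.69909	0.314627	0.130333	5.67455
21.8793	5.23211	4.81829	0.281009	0.132808	4.79997
23.1186	4.45523	4.06964	0.25046	0.135134	4.0564
24.4282	3.79569	3.4351	0.223283	0.137305	3.42603
25.8119	3.23742	2.89847	0.199635	0.139317	2.89282
27.274	2.76609	2.44537	0.179544	0.141169	2.44255
28.819	2.36899	2.0632	0.162933	0.14286	2.06273
30	2.1199	1.82298	0.152931	0.143992	1.82399
30.4514	2.03484	1.74088	0.149567	0.144391	1.74239
32.1763	1.75076	1.46725	0.13775	0.145763	1.47045
33.999	1.50893	1.23517	0.126777	0.146977	1.23983
35.9249	1.30374	1.03916	0.116546	0.148036	1.04509
37.9598	1.13014	0.874233	0.106971	0.14894	0.881296
40	0.990386	0.742307	0.09842	0.149659	0.750335
40.1101	0.983659	0.735981	0.0979842	0.149693	0.744057
42.3821	0.859563	0.619954	0.0893121	0.150296	0.628953
44.7828	0.753708	0.522033	0.080924	0.150751	0.531885
47.3196	0.663136	0.439072	0.0730027	0.151061	0.449727
50	0.5854	0.3685	0.0656731	0.151226	0.379919
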