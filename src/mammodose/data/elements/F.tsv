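# element F  Z=9  A=18.998  K_edge_keV=0.6971
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	5631.39	5628.09	3.29519	0.00314607	5603.23
1.05665	4945.72	4942.43	3.28257	0.00350419	4920.99
1.1165	4334.81	4331.55	3.25754	0.00390208	4313.14
1.17974	3792.14	3788.92	3.22112	0.00434391	3773.18
1.24657	3311.43	3308.25	3.17437	0.00483426	3294.88
1.31718	2886.72	2883.59	3.11833	0.00537808	2872.28
1.39179	2512.4	2509.34	3.05404	0.00598078	2499.84
1.47063	2183.25	2180.27	2.98253	0.00664819	2172.34
1.5	2075.22	2072.26	2.95531	0.00690466	2064.84
1.55394	1894.27	1891.38	2.8799	0.00738659	1884.8
1.64196	1640.57	1637.88	2.68089	0.00820274	1632.36
1.73497	1418.48	1416.04	2.42709	0.00910382	1411.39
1.83325	1224.61	1222.43	2.16825	0.0100975	1218.48
1.93709	1055.73	1053.77	1.95311	0.0111918	1050.45
2	968.067	966.188	1.86711	0.0118759	963.227
2.04682	908.899	907.067	1.81949	0.0123951	904.354
2.16276	781.284	779.554	1.71602	0.0137161	777.378
2.28527	670.648	669.008	1.62449	0.0151638	667.295
2.41472	574.995	573.436	1.5424	0.0167472	572.12
2.5515	492.503	491.017	1.46732	0.0184752	490.041
2.69603	421.522	420.105	1.39688	0.0203565	419.414
2.84875	360.569	359.218	1.32879	0.0223996	358.766
3	311.287	309.997	1.26506	0.0244718	309.66
3.01012	308.321	307.036	1.26088	0.0246119	306.703
3.18062	263.451	262.23	1.19395	0.0270001	261.961
3.36079	224.886	223.727	1.12983	0.0295695	223.51
3.55116	184.785	183.684	1.06871	0.0323238	183.515
3.75232	153.189	152.143	1.0108	0.0352648	152.011
3.96487	128.8	127.805	0.956145	0.0383916	127.7
4	125.401	124.414	0.947661	0.0389093	124.313
4.18946	109.291	108.348	0.901497	0.0417012	108.264
4.42677	93.0867	92.1955	0.845959	0.0451871	92.1279
4.67753	79.3141	78.4686	0.796651	0.0488399	78.4143
4.94249	67.3862	66.5735	0.760026	0.0526468	66.53
5	65.0748	64.2669	0.754483	0.0534643	64.2255
5.22245	56.8963	56.0988	0.740911	0.0565917	56.0643
5.51828	47.813	47.0204	0.731929	0.0606554	46.9933
5.83086	40.2191	39.4352	0.719097	0.0648157	39.4139
6	36.8516	36.0778	0.706838	0.0670047	36.0589
6.16115	34.0426	33.2839	0.689655	0.0690479	33.2671
6.51015	28.9709	28.2599	0.637679	0.0733257	28.2467
6.87892	24.7307	24.0785	0.574559	0.0776216	24.0681
7.26858	21.1381	20.5393	0.516851	0.0819079	20.5313
7.68031	18.0424	17.4951	0.461147	0.0861577	17.4889
8	16.0181	15.4958	0.433053	0.0892646	15.4908
8.11536	15.3549	14.8393	0.425251	0.0903454	14.8347
8.57506	13.0285	12.5373	0.396798	0.0944479	12.534
9.06079	11.0392	10.5703	0.370513	0.0984448	10.5681
9.57404	9.35403	8.9057	0.346016	0.102319	8.9045
10	8.21466	7.78166	0.327711	0.105285	7.7811
10.1164	7.93743	7.50861	0.322766	0.106058	7.5082
10.6894	6.73842	6.32887	0.299894	0.109651	6.32914
11.2949	5.72001	5.3287	0.27821	0.113092	5.32955
11.9347	4.85768	4.48322	0.258085	0.116379	4.48458
12.6108	4.12913	3.77021	0.239407	0.119509	3.77204
13.3251	3.5145	3.1701	0.221924	0.122484	3.17234
14.0799	2.99668	2.66574	0.205635	0.125307	2.66838
14.8775	2.56	2.24231	0.189712	0.12798	2.24532
15	2.50108	2.18538	0.187334	0.128366	2.18844
15.7202	2.18908	1.88425	0.17432	0.130508	1.88762
16.6107	1.87243	1.57938	0.16016	0.132892	1.5831
17.5516	1.60495	1.32271	0.147111	0.135135	1.32678
18.5458	1.38113	1.10882	0.135078	0.13724	1.11324
19.5963	1.19544	0.932251	0.123981	0.139207	0.937021
20	1.13532	0.875321	0.120097	0.139899	0.880221
20.7063	1.04096	0.786178	0.113743	0.141035	0.791303
21.8793	0.907914	0.660914	0.104274	0.142725	0.666403
23.1186	0.793673	0.553881	0.0955162	0.144276	0.559743
24.4282	0.69624	0.463111	0.0874447	0.145685	0.469354
25.8119	0.613646	0.386699	0.0799959	0.146951	0.393335
27.274	0.544048	0.322874	0.0731014	0.148073	0.329913
28.819	0.485801	0.270029	0.0667229	0.149049	0.277482
30	0.449657	0.237609	0.0623783	0.149669	0.245372
30.4514	0.437376	0.22667	0.0608262	0.14988	0.234549
32.1763	0.396095	0.190134	0.0553956	0.150565	0.198451
33.999	0.360576	0.159069	0.0504019	0.151106	0.167833
35.9249	0.330146	0.132831	0.0458115	0.151503	0.142055
37.9598	0.304224	0.11087	0.0415935	0.151761	0.120564
40	0.283324	0.0935405	0.0379054	0.151878	0.103691
40.1101	0.282319	0.0927182	0.0377199	0.151881	0.102893
42.3821	0.263558	0.0775201	0.03417	0.151868	0.0881848
44.7828	0.247309	0.0646579	0.0309247	0.151726	0.0758223
47.3196	0.233393	0.0539715	0.0279622	0.151459	0.0656445
50	0.221661	0.0453266	0.0252616	0.151073	0.0575164
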