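# element Be  Z=4  A=9.0122  K_edge_keV=0.112
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	585.426	585.049	0.363533	0.0127185	582.498
1.05665	496.105	495.73	0.360525	0.0140137	493.624
1.1165	420.359	419.986	0.357242	0.0154202	418.257
1.17974	356.127	355.757	0.353668	0.0169432	354.347
1.24657	301.663	301.295	0.349785	0.0185874	300.155
1.31718	255.482	255.116	0.34558	0.0203566	254.205
1.39179	216.327	215.963	0.341038	0.0222537	215.245
1.47063	183.128	182.768	0.336148	0.0242801	182.212
1.5	172.489	172.129	0.334307	0.0250389	171.626
1.55394	154.96	154.602	0.330902	0.026436	154.185
1.64196	131.014	130.66	0.325294	0.0287198	130.359
1.73497	110.695	110.345	0.319322	0.0311283	110.142
1.83325	93.491	93.1444	0.312989	0.0336563	93.0236
1.93709	78.9617	78.6191	0.306302	0.0362968	78.5669
2	71.6082	71.2681	0.302265	0.0378767	71.2502
2.04682	66.7145	66.3762	0.299272	0.0390411	66.3756
2.16276	56.3157	55.9819	0.291917	0.0418786	55.9815
2.28527	47.4852	47.1562	0.284258	0.0447976	47.1559
2.41472	40.0034	39.6793	0.276322	0.047785	39.6792
2.5515	33.6788	33.3599	0.268139	0.0508275	33.3598
2.69603	28.3459	28.0322	0.259745	0.0539115	28.0323
2.84875	23.8626	23.5544	0.251177	0.0570238	23.5545
3	20.3187	20.0158	0.24301	0.0599609	20.016
3.01012	20.1082	19.8056	0.242475	0.0601522	19.8058
3.18062	16.9529	16.656	0.233678	0.0632859	16.6562
3.36079	14.2872	13.9959	0.224827	0.0664159	13.9963
3.55116	12.0368	11.7513	0.21596	0.0695353	11.7517
3.75232	10.1396	9.85987	0.207114	0.0726393	9.86034
3.96487	8.54392	8.26988	0.198324	0.0757252	8.27041
4	8.31344	8.0403	0.196923	0.0762175	8.04084
4.18946	7.19692	6.92851	0.189618	0.0787924	6.92911
4.42677	6.05565	5.79279	0.181025	0.0818419	5.79345
4.67753	5.10096	4.84333	0.172756	0.084876	4.84407
4.94249	4.31184	4.05883	0.165107	0.0878975	4.05965
5	4.16496	3.91303	0.163398	0.0885306	3.91387
5.22245	3.66546	3.41791	0.156634	0.0909096	3.41881
5.51828	3.13095	2.88888	0.148159	0.0939152	2.88986
5.83086	2.67702	2.43972	0.140386	0.0969162	2.44079
6	2.46568	2.23078	0.136428	0.098472	2.2319
6.16115	2.28224	2.04952	0.132808	0.0999132	2.05068
6.51015	1.93856	1.71005	0.125612	0.102905	1.71132
6.87892	1.64615	1.42016	0.120102	0.10589	1.42154
7.26858	1.40042	1.17682	0.114733	0.108862	1.17832
7.68031	1.20011	0.975566	0.112728	0.111813	0.97719
8	1.07486	0.850683	0.1102	0.11398	0.852406
8.11536	1.03457	0.811075	0.108761	0.114736	0.812834
8.57506	0.895719	0.675133	0.102967	0.117619	0.677034
9.06079	0.780027	0.562632	0.0969451	0.12045	0.564687
9.57404	0.683952	0.469865	0.0908726	0.123214	0.472081
10	0.619596	0.408131	0.0861231	0.125342	0.410482
10.1164	0.603987	0.393103	0.0849857	0.125898	0.39549
10.6894	0.5362	0.328068	0.079644	0.128488	0.330637
11.2949	0.478472	0.273063	0.0744385	0.130971	0.275823
11.9347	0.429666	0.226947	0.0693869	0.133332	0.229909
12.6108	0.388613	0.188545	0.0645067	0.135562	0.191718
13.3251	0.354165	0.156701	0.0598139	0.137651	0.160096
14.0799	0.325237	0.130324	0.0553222	0.139591	0.133951
14.8775	0.30082	0.108399	0.0510422	0.141378	0.112269
15	0.297511	0.105457	0.0504236	0.141631	0.109363
15.7202	0.280062	0.0900519	0.0470021	0.143008	0.0941733
16.6107	0.262578	0.0748704	0.0432266	0.144481	0.0792546
17.5516	0.247933	0.0624402	0.039696	0.145797	0.0670974
18.5458	0.235625	0.0522748	0.0363928	0.146958	0.0572156
19.5963	0.225215	0.0439455	0.0333019	0.147968	0.0491804
20	0.221765	0.041252	0.0322092	0.148304	0.0465983
20.7063	0.216219	0.0369728	0.0304157	0.148831	0.0425123
21.8793	0.208063	0.030768	0.027743	0.149552	0.0366228
23.1186	0.200651	0.0252409	0.0252748	0.150136	0.0314217
24.4282	0.193933	0.020344	0.023	0.150588	0.0268616
25.8119	0.187873	0.0160508	0.020907	0.150915	0.022916
27.274	0.18263	0.0125244	0.0189843	0.151122	0.019748
28.819	0.178986	0.0105531	0.0172207	0.151212	0.0181459
30	0.177134	0.00989647	0.0160292	0.151209	0.0177652
30.4514	0.176438	0.00963972	0.0156053	0.151193	0.0176125
32.1763	0.173525	0.00833102	0.014127	0.151067	0.0166944
33.999	0.170553	0.00693521	0.0127776	0.15084	0.0156996
35.9249	0.167735	0.00567044	0.0115495	0.150515	0.0148462
37.9598	0.165285	0.00475276	0.0104347	0.150097	0.01435
40	0.163379	0.0042884	0.00947332	0.149617	0.014295
40.1101	0.163284	0.00426877	0.00942535	0.14959	0.0142971
42.3821	0.1612	0.00368967	0.00851441	0.148996	0.0141585
44.7828	0.159049	0.00303715	0.00769263	0.148319	0.0139555
47.3196	0.157006	0.00249325	0.00695005	0.147562	0.0138695
50	0.155215	0.00220751	0.00627805	0.146729	0.0140497
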