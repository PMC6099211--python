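# element Li  Z=3  A=6.94  K_edge_keV=0.0548
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	224.537	224.253	0.266171	0.0171979	223.414
1.05665	188.95	188.668	0.263189	0.0187367	188.006
1.1165	159.06	158.78	0.259989	0.0203704	158.265
1.17974	133.938	133.659	0.256567	0.0220976	133.268
1.24657	112.811	112.534	0.252919	0.023916	112.247
1.31718	95.0322	94.7573	0.249048	0.0258223	94.557
1.39179	80.0624	79.7896	0.244954	0.0278119	79.6621
1.47063	67.4502	67.1797	0.240642	0.0298797	67.1129
1.5	63.4246	63.1549	0.239044	0.0306397	63.1075
1.55394	56.8036	56.5355	0.236121	0.0320198	56.5196
1.64196	47.7837	47.5181	0.2314	0.0342257	47.5181
1.73497	40.1682	39.9052	0.22649	0.036491	39.9053
1.83325	33.7653	33.5051	0.221407	0.0388095	33.5052
1.93709	28.4073	28.15	0.216166	0.0411756	28.1501
2	25.7202	25.4645	0.21306	0.042568	25.4647
2.04682	23.9385	23.6842	0.210783	0.0435846	23.6843
2.16276	20.1524	19.9011	0.205277	0.0460329	19.9012
2.28527	16.9395	16.6913	0.199664	0.0485184	16.6915
2.41472	14.2219	13.9769	0.193963	0.0510406	13.9771
2.5515	11.9314	11.6896	0.18819	0.0536003	11.6899
2.69603	10.0087	9.77017	0.182359	0.0562	9.77045
2.84875	8.40326	8.16794	0.176485	0.0588433	8.16825
3	7.14644	6.91413	0.17094	0.0613689	6.91447
3.01012	7.07224	6.84013	0.170578	0.0615348	6.84048
3.18062	5.96098	5.73205	0.16465	0.0642796	5.73244
3.36079	5.0236	4.79781	0.158708	0.0670831	4.79824
3.55116	4.23405	4.01134	0.15276	0.0699502	4.01182
3.75232	3.57079	3.35109	0.14681	0.072885	3.35162
3.96487	3.01607	2.79931	0.140865	0.0758904	2.79989
4	2.93632	2.72003	0.139914	0.0763782	2.72062
4.18946	2.55007	2.33618	0.134928	0.0789675	2.33681
4.42677	2.15564	1.94452	0.129006	0.0821154	1.94522
4.67753	1.82749	1.61875	0.123407	0.0853307	1.61952
4.94249	1.5592	1.35201	0.118581	0.0886072	1.35285
5	1.5095	1.30282	0.117375	0.0893022	1.30368
5.22245	1.34107	1.13693	0.112212	0.0919361	1.13784
5.51828	1.16187	0.960958	0.105605	0.0953058	0.961963
5.83086	1.01015	0.811572	0.0998781	0.0987019	0.812671
6	0.939206	0.741801	0.0969357	0.100469	0.742951
6.16115	0.877289	0.680953	0.0942289	0.102108	0.682152
6.51015	0.760615	0.566149	0.0889618	0.105505	0.567456
6.87892	0.662668	0.467666	0.0861293	0.108873	0.469089
7.26858	0.580576	0.385089	0.083296	0.112191	0.386637
7.68031	0.515048	0.317182	0.0824288	0.115437	0.318861
8	0.473744	0.275388	0.080573	0.117782	0.277171
8.11536	0.460254	0.262217	0.0794446	0.118592	0.264037
8.57506	0.413927	0.217411	0.0748788	0.121637	0.21938
9.06079	0.375433	0.180758	0.0701225	0.124553	0.182884
9.57404	0.34334	0.150675	0.0653388	0.127326	0.152967
10	0.321567	0.130542	0.0616178	0.129407	0.13297
10.1164	0.316277	0.125609	0.0607248	0.129943	0.128075
10.6894	0.293294	0.104338	0.0565601	0.132396	0.106986
11.2949	0.273701	0.086473	0.0525506	0.134677	0.0893121
11.9347	0.257104	0.0716128	0.0487071	0.136784	0.0746517
12.6108	0.243085	0.0593306	0.0450385	0.138716	0.0625781
13.3251	0.231221	0.0491974	0.0415506	0.140473	0.0526623
14.0799	0.221104	0.0407993	0.0382467	0.142058	0.0444906
14.8775	0.212346	0.0337418	0.0351276	0.143477	0.0376684
15	0.211134	0.0327817	0.034679	0.143674	0.0367441
15.7202	0.204772	0.0278303	0.0322088	0.144733	0.0320016
16.6107	0.198473	0.0231338	0.0295052	0.145834	0.0275592
17.5516	0.193192	0.0194092	0.0269969	0.146786	0.0240981
18.5458	0.188647	0.0163856	0.0246664	0.147595	0.0213479
19.5963	0.184604	0.0138372	0.022499	0.148268	0.0190827
20	0.183195	0.0129751	0.0217356	0.148484	0.018328
20.7063	0.180869	0.0115717	0.0204856	0.148811	0.0171105
21.8793	0.177359	0.00949998	0.0186288	0.149231	0.0153422
23.1186	0.174069	0.00761618	0.0169207	0.149532	0.0137721
24.4282	0.17099	0.00591717	0.0153522	0.149721	0.0123972
25.8119	0.168129	0.00441298	0.0139144	0.149802	0.0112275
27.274	0.165599	0.00322048	0.0125985	0.14978	0.01038
28.819	0.163836	0.00277857	0.0113962	0.149661	0.0102935
30	0.16293	0.00282935	0.0105866	0.149514	0.0106099
30.4514	0.162574	0.00282781	0.0102992	0.149447	0.0107086
32.1763	0.160982	0.00253984	0.00929889	0.149143	0.0107967
33.999	0.15925	0.00210718	0.00838909	0.148753	0.0107504
35.9249	0.157528	0.00168374	0.00756406	0.14828	0.0107233
37.9598	0.155965	0.00141945	0.00681793	0.147728	0.0108651
40	0.154694	0.00138547	0.00617675	0.147131	0.0112258
40.1101	0.154629	0.00138604	0.00614482	0.147098	0.0112474
42.3821	0.15319	0.00125509	0.00553951	0.146395	0.0115412
44.7828	0.151647	0.00103115	0.00499528	0.145621	0.0117509
47.3196	0.150117	0.000833645	0.00450511	0.144778	0.0119953
50	0.148693	0.000760929	0.00406292	0.143869	0.0123723
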