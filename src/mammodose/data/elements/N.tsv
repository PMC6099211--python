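# element N  Z=7  A=14.007  K_edge_keV=0.4099
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	3270.36	3268.51	1.84222	0.00538889	3254.01
1.05665	2817.41	2815.57	1.83355	0.00599303	2803.32
1.1165	2425.09	2423.27	1.81886	0.00666206	2412.97
1.17974	2085.68	2083.88	1.79862	0.00740227	2075.26
1.24657	1792.36	1790.58	1.77331	0.00822044	1783.4
1.31718	1539.14	1537.38	1.74341	0.00912377	1531.44
1.39179	1320.74	1319.02	1.70941	0.0101199	1314.14
1.47063	1132.56	1130.88	1.67177	0.0112169	1126.9
1.5	1071.62	1069.95	1.65747	0.0116368	1066.26
1.55394	970.482	968.85	1.6196	0.0124233	965.63
1.64196	830.744	829.207	1.52332	0.0137476	826.59
1.73497	710.445	709.028	1.40218	0.0151989	706.893
1.83325	607.046	605.75	1.27893	0.0167862	604.011
1.93709	518.305	517.111	1.17561	0.0185185	515.713
2	472.761	471.608	1.13319	0.0195931	470.397
2.04682	442.244	441.114	1.10903	0.0204044	440.033
2.16276	377.071	375.993	1.05583	0.0224523	375.186
2.28527	321.28	320.247	1.00778	0.0246698	319.673
2.41472	273.571	272.58	0.963703	0.0270635	272.203
2.5515	232.814	231.862	0.922495	0.0296388	231.65
2.69603	198.03	197.115	0.883088	0.0323994	197.04
2.84875	168.369	167.489	0.84448	0.035347	167.448
3	144.527	143.681	0.808131	0.0382843	143.647
3.01012	143.097	142.252	0.805748	0.0384811	142.219
3.18062	121.547	120.738	0.767273	0.0417984	120.711
3.36079	103.172	102.397	0.729866	0.0452931	102.375
3.55116	87.5244	86.7818	0.693639	0.0489558	86.7648
3.75232	74.2158	73.5043	0.658695	0.0527743	73.4907
3.96487	62.9089	62.227	0.62513	0.0567329	62.2163
4	61.2644	60.5871	0.61989	0.0573785	60.5768
4.18946	53.3137	52.6612	0.591742	0.0608132	52.6527
4.42677	45.1679	44.5448	0.558085	0.0649939	44.5382
4.67753	38.2403	37.644	0.52707	0.0692514	37.6389
4.94249	32.3411	31.7663	0.501233	0.0735609	31.7624
5	31.2178	30.6467	0.496668	0.0744699	30.643
5.22245	27.297	26.7367	0.482378	0.0778962	26.7339
5.51828	22.9938	22.4441	0.467533	0.0822316	22.442
5.83086	19.3818	18.8439	0.451318	0.0865419	18.8426
6	17.7574	17.2277	0.440849	0.088761	17.2267
6.16115	16.3863	15.8665	0.429018	0.0908036	15.8657
6.51015	13.8844	13.3908	0.398644	0.0949957	13.3905
6.87892	11.7796	11.3158	0.364696	0.0991001	11.3159
7.26858	9.99889	9.56542	0.330363	0.103102	9.56591
7.68031	8.48785	8.07969	0.301169	0.10699	8.0805
8	7.51525	7.12212	0.283341	0.109789	7.12315
8.11536	7.19993	6.81107	0.278106	0.110756	6.81217
8.57506	6.09936	5.72599	0.258979	0.114395	5.72736
9.06079	5.16605	4.80687	0.241273	0.117906	4.80851
9.57404	4.38229	4.03623	0.22477	0.121288	4.03811
10	3.85669	3.52035	0.212467	0.123869	3.52242
10.1164	3.72912	3.39521	0.20936	0.124542	3.39734
10.6894	3.17633	2.85365	0.195005	0.127673	2.85602
11.2949	2.70609	2.394	0.181401	0.130681	2.39661
11.9347	2.30794	2.00582	0.168553	0.133571	2.00867
12.6108	1.97221	1.67941	0.156458	0.136342	1.68251
13.3251	1.69009	1.40599	0.145103	0.138998	1.40934
14.0799	1.45374	1.17773	0.134471	0.141536	1.18135
14.8775	1.25648	0.987795	0.124731	0.143956	0.991688
15	1.23009	0.962419	0.123363	0.144306	0.966353
15.7202	1.08996	0.827963	0.115745	0.146255	0.83214
16.6107	0.947015	0.691369	0.107216	0.148429	0.695844
17.5516	0.826046	0.576436	0.0991361	0.150474	0.581219
18.5458	0.725136	0.481258	0.0914924	0.152385	0.486363
19.5963	0.642234	0.403806	0.0842713	0.154157	0.409245
20	0.615719	0.37924	0.0817034	0.154776	0.384806
20.7063	0.574171	0.340914	0.0774723	0.155785	0.3467
21.8793	0.515142	0.286752	0.071125	0.157265	0.2929
23.1186	0.463939	0.240136	0.0652099	0.158593	0.246658
24.4282	0.419806	0.200334	0.0597047	0.159768	0.207243
25.8119	0.382029	0.166654	0.0545882	0.160787	0.173963
27.274	0.349955	0.138463	0.0498399	0.161651	0.146187
28.819	0.323001	0.1152	0.0454402	0.162362	0.123349
30	0.306291	0.101066	0.0424416	0.162783	0.109534
30.4514	0.300626	0.0963357	0.0413702	0.16292	0.104925
32.1763	0.281585	0.0806359	0.03762	0.163329	0.0896763
33.999	0.265153	0.0673846	0.0341752	0.163593	0.0768886
35.9249	0.250967	0.0562332	0.0310174	0.163716	0.0662126
37.9598	0.23872	0.0468885	0.0281283	0.163703	0.0573548
40	0.228643	0.0394581	0.0256156	0.163569	0.0503972
40.1101	0.228152	0.0391031	0.0254896	0.163559	0.0500672
42.3821	0.218899	0.0325238	0.0230862	0.163289	0.0439964
44.7828	0.210781	0.026984	0.0209002	0.162897	0.038975
47.3196	0.203799	0.0224977	0.0189117	0.162389	0.0350168
50	0.197953	0.0190799	0.0171027	0.16177	0.0321357
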