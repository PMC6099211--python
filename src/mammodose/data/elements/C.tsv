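# element C  Z=6  A=12.011  K_edge_keV=0.2842
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	2211	2210.36	0.632187	0.00719009	2199.95
1.05665	1895.1	1894.47	0.629533	0.00798417	1885.63
1.1165	1623.19	1622.56	0.626599	0.00886074	1615.08
1.17974	1389.36	1388.72	0.623359	0.00982716	1382.41
1.24657	1188.44	1187.8	0.619783	0.0108912	1182.49
1.31718	1015.94	1015.31	0.615844	0.0120609	1010.86
1.39179	867.972	867.347	0.611509	0.0133447	863.632
1.47063	741.138	740.516	0.606748	0.0147511	737.432
1.5	700.2	699.58	0.60493	0.0152873	696.699
1.55394	632.464	631.846	0.601528	0.0162887	629.302
1.64196	539.307	538.693	0.595814	0.017966	536.61
1.73497	459.518	458.908	0.589574	0.0197914	457.22
1.83325	391.243	390.638	0.582775	0.0217726	389.287
1.93709	332.874	332.275	0.575386	0.0239167	331.21
2	303	302.404	0.570817	0.0252376	301.485
2.04682	283.015	282.422	0.567377	0.02623	281.6
2.16276	240.444	239.856	0.558721	0.0287172	239.241
2.28527	204.136	203.555	0.549398	0.0313818	203.116
2.41472	173.209	172.635	0.53939	0.034225	172.343
2.5515	146.895	146.329	0.528687	0.0372461	146.16
2.69603	124.528	123.971	0.517286	0.0404418	123.906
2.84875	105.535	104.986	0.505194	0.0438059	104.977
3	90.33	89.7897	0.493224	0.04711	89.7819
3.01012	89.4198	88.88	0.492425	0.0473296	88.8724
3.18062	75.7381	75.2081	0.479007	0.0510009	75.202
3.36079	64.1186	63.5988	0.464976	0.054805	63.5941
3.55116	54.2579	53.7488	0.45038	0.0587243	53.7452
3.75232	45.8959	45.3978	0.435278	0.0627389	45.3951
3.96487	38.8093	38.3227	0.419738	0.0668271	38.3207
4	37.78	37.2953	0.417214	0.0674869	37.2933
4.18946	32.7986	32.3238	0.403837	0.0709657	32.3223
4.42677	27.6992	27.2364	0.38766	0.0751312	27.2354
4.67753	23.3885	22.9379	0.371294	0.0793002	22.9373
4.94249	19.756	19.3177	0.354832	0.0834504	19.3175
5	19.07	18.6343	0.351372	0.0843175	18.6341
5.22245	16.6994	16.2735	0.338364	0.0875613	16.2735
5.51828	14.1213	13.7077	0.321979	0.0916147	13.708
5.83086	11.9438	11.5425	0.305762	0.0955954	11.543
6	10.95	10.5549	0.297438	0.0976285	10.5556
6.16115	10.102	9.71269	0.28979	0.0994914	9.71344
6.51015	8.54059	8.16316	0.274134	0.103294	8.1641
6.87892	7.22039	6.85454	0.258852	0.106997	6.85567
7.26858	6.10727	5.75267	0.243997	0.110597	5.75399
7.68031	5.17094	4.82724	0.229608	0.114094	4.82873
8	4.576	4.2401	0.219278	0.116617	4.24173
8.11536	4.38436	4.05115	0.215718	0.11749	4.05282
8.57506	3.71783	3.39469	0.202349	0.120785	3.39654
9.06079	3.15574	2.84224	0.189515	0.123983	2.84427
9.57404	2.68628	2.38197	0.177225	0.127086	2.38419
10	2.373	2.07563	0.167902	0.129471	2.078
10.1164	2.29713	2.00141	0.16562	0.130096	2.00383
10.6894	1.96775	1.67971	0.155022	0.133013	1.68233
11.2949	1.68697	1.40625	0.144878	0.135837	1.40908
11.9347	1.44907	1.17532	0.135186	0.138566	1.17837
12.6108	1.24855	0.981405	0.125943	0.141197	0.98469
13.3251	1.0803	0.819429	0.117145	0.143725	0.822958
14.0799	0.939717	0.684789	0.108785	0.146143	0.688573
14.8775	0.822725	0.57342	0.100859	0.148445	0.577473
15	0.8071	0.558607	0.0997154	0.148778	0.5627
15.7202	0.724025	0.480029	0.0933721	0.150624	0.484361
16.6107	0.638982	0.399987	0.0863224	0.152672	0.404614
17.5516	0.566871	0.332613	0.0796765	0.154582	0.337546
18.5458	0.506758	0.277004	0.0734072	0.156347	0.282256
19.5963	0.45761	0.232155	0.0674929	0.157962	0.237741
20	0.442	0.218088	0.0653905	0.158521	0.2238
20.7063	0.417556	0.196206	0.061927	0.159424	0.202137
21.8793	0.382634	0.165172	0.0567344	0.160728	0.171462
23.1186	0.352103	0.138325	0.0519039	0.161874	0.144988
24.4282	0.325566	0.115285	0.0474198	0.162861	0.122333
25.8119	0.302661	0.095704	0.0432657	0.163691	0.103149
27.274	0.283067	0.0792745	0.039425	0.164367	0.0871305
28.819	0.266503	0.0657298	0.0358805	0.164892	0.074009
30	0.2562	0.0575446	0.0334736	0.165182	0.06614
30.4514	0.252705	0.0548199	0.032615	0.16527	0.0635346
32.1763	0.240941	0.0458222	0.0296138	0.165505	0.0549845
33.999	0.230744	0.0382767	0.0268636	0.165603	0.0478987
35.9249	0.221867	0.0319482	0.0243502	0.165569	0.0420415
37.9598	0.214105	0.0266389	0.0220588	0.165408	0.0372148
40	0.2076	0.0223853	0.0200735	0.165141	0.03343
40.1101	0.207279	0.0221806	0.0199742	0.165124	0.0332502
42.3821	0.201193	0.0183849	0.0180842	0.164724	0.0299587
44.7828	0.195785	0.0152026	0.0163718	0.164211	0.0272907
47.3196	0.19108	0.012671	0.0148185	0.16359	0.0252829
50	0.1871	0.0108255	0.013408	0.162867	0.02397
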