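# element Mg  Z=12  A=24.305  K_edge_keV=1.305
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	821.583	818.978	2.59922	0.00582763	817.475
1.05665	752.589	749.995	2.5871	0.00642969	748.826
1.1165	686.372	683.797	2.56785	0.00708565	682.94
1.17974	623.334	620.784	2.54205	0.00779867	620.217
1.24657	563.773	561.254	2.51027	0.00857179	560.954
1.30487	517.012	514.523	2.47977	0.00926077	514.427
1.30513	5853.64	5851.15	2.47963	0.00926389	5766.76
1.31718	5752.23	5749.74	2.47308	0.00940784	5667.57
1.39179	5160.23	5157.79	2.43105	0.0103094	5088.03
1.47063	4612.04	4609.64	2.38476	0.0112788	4550.64
1.5	4425.97	4423.59	2.36723	0.0116435	4368.08
1.55394	4107.37	4105.03	2.32159	0.0123178	4055.31
1.64196	3645.24	3643.02	2.20714	0.013428	3601.26
1.73497	3224.37	3222.29	2.06377	0.0146104	3187.33
1.83325	2842.8	2840.87	1.91791	0.0158656	2811.7
1.93709	2497.68	2495.87	1.79518	0.0171937	2471.61
2	2313.14	2311.38	1.74437	0.0179974	2289.62
2.04682	2186.17	2184.43	1.71524	0.0185944	2164.34
2.16276	1905.15	1903.48	1.65095	0.0200674	1886.91
2.28527	1654.01	1652.39	1.59275	0.0216119	1638.78
2.41472	1431.75	1430.19	1.53934	0.0232272	1419.04
2.5515	1236.74	1235.22	1.48943	0.0249128	1226.11
2.69603	1066.91	1065.44	1.44182	0.0266686	1058
2.84875	919.971	918.548	1.39533	0.028495	912.478
3	800.737	799.355	1.35171	0.0302751	794.34
3.01012	793.556	792.176	1.34886	0.0303931	787.223
3.18062	684.208	682.872	1.30284	0.0323649	678.831
3.36079	589.146	587.854	1.25821	0.0344131	584.561
3.55116	460.073	458.821	1.21507	0.0365417	456.389
3.75232	367.866	366.654	1.17351	0.0387553	364.814
3.96487	305.184	304.009	1.13329	0.0410594	302.566
4	296.982	295.814	1.12682	0.0414371	294.422
4.18946	259.056	257.92	1.09192	0.0434599	256.762
4.42677	221.856	220.76	1.04992	0.0459631	219.822
4.67753	190.592	189.532	1.01126	0.048575	188.77
4.94249	163.38	162.349	0.979586	0.0513015	161.731
5	158.053	157.027	0.974133	0.0518889	156.436
5.22245	139.248	138.236	0.957734	0.0541471	137.739
5.51828	118.363	117.365	0.941629	0.0571155	116.965
5.83086	100.602	99.6189	0.923243	0.0602083	99.298
6	92.5357	91.5635	0.91038	0.0618624	91.2769
6.16115	85.6958	84.7374	0.894971	0.0634252	84.4793
6.51015	73.154	72.2343	0.852928	0.0667634	72.0263
6.87892	62.5179	61.6443	0.803441	0.0702173	61.4765
7.26858	53.4465	52.6116	0.761106	0.0737784	52.4764
7.68031	45.6502	44.8564	0.716338	0.0774351	44.7476
8	40.5766	39.807	0.689396	0.0801948	39.7146
8.11536	38.9212	38.159	0.681039	0.081173	38.0717
8.57506	33.1228	32.3884	0.649414	0.0849748	32.3187
9.06079	28.1567	27.4493	0.618506	0.0888209	27.3938
9.57404	23.9247	23.2438	0.58817	0.0926895	23.1998
10	21.0395	20.3792	0.564535	0.0957467	20.3426
10.1164	20.3342	19.6824	0.555261	0.0965578	19.6476
10.6894	17.281	16.668	0.51258	0.100402	16.6406
11.2949	14.6809	14.1043	0.472418	0.104199	14.083
11.9347	12.4717	11.9276	0.436113	0.107925	11.9112
12.6108	10.5968	10.0821	0.403124	0.111561	10.0697
13.3251	9.00674	8.5193	0.372358	0.115087	8.5101
14.0799	7.65936	7.19706	0.343813	0.118487	7.19052
14.8775	6.51714	6.07918	0.316213	0.121747	6.07482
15	6.36259	5.92825	0.312111	0.12222	5.92419
15.7202	5.54532	5.13086	0.2896	0.124858	5.12832
16.6107	4.7168	4.32391	0.265074	0.127813	4.32289
17.5516	4.01455	3.64137	0.24257	0.130606	3.64164
18.5458	3.42237	3.06713	0.222013	0.133236	3.06849
19.5963	2.9252	2.58619	0.20331	0.135702	2.58851
20	2.76251	2.4291	0.196839	0.136573	2.43174
20.7063	2.50709	2.1828	0.186286	0.138005	2.18595
21.8793	2.1494	1.83867	0.170576	0.140145	1.84258
23.1186	1.84432	1.54611	0.156082	0.142126	1.5507
24.4282	1.58541	1.2986	0.142863	0.14395	1.30383
25.8119	1.36652	1.09013	0.130773	0.145617	1.09595
27.274	1.182	0.915243	0.119626	0.147131	0.921644
28.819	1.02695	0.769103	0.109356	0.148491	0.776057
30	0.930006	0.678233	0.102387	0.149387	0.685581
30.4514	0.896932	0.647332	0.0999017	0.149699	0.654826
32.1763	0.78612	0.544153	0.0912112	0.150756	0.552181
33.999	0.691406	0.45653	0.0832146	0.151661	0.46509
35.9249	0.610866	0.382605	0.0758455	0.152416	0.391696
37.9598	0.542731	0.320663	0.0690463	0.153022	0.330288
40	0.488034	0.271505	0.0630689	0.153459	0.281641
40.1101	0.485407	0.269161	0.0627674	0.153479	0.279324
42.3821	0.436818	0.226047	0.0569812	0.153789	0.236752
44.7828	0.395201	0.189578	0.0516679	0.153955	0.200832
47.3196	0.359559	0.158782	0.0467983	0.153979	0.17059
50	0.329064	0.132856	0.0423436	0.153865	0.145224
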