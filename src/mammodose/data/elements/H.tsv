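# element H  Z=1  A=1.008  K_edge_keV=0.0136
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	7.217	6.81983	0.346734	0.0504342	6.81993
1.05665	6.03155	5.63443	0.341572	0.0555528	5.63454
1.1165	5.0645	4.66743	0.335968	0.0611059	4.66756
1.17974	4.27237	3.87535	0.329903	0.0671125	3.87551
1.24657	3.62087	3.22392	0.323361	0.0735885	3.2241
1.31718	3.08288	2.68601	0.316328	0.0805458	2.68621
1.39179	2.63688	2.24009	0.308797	0.0879916	2.24033
1.47063	2.26569	1.86899	0.300764	0.0959271	1.86927
1.5	2.148	1.75135	0.29776	0.0988934	1.75163
1.55394	1.95347	1.55689	0.292236	0.104347	1.5572
1.64196	1.68632	1.28986	0.283223	0.113237	1.29022
1.73497	1.4621	1.06577	0.273747	0.122576	1.06619
1.83325	1.27784	0.881668	0.263839	0.132332	0.882139
1.93709	1.12979	0.733791	0.253537	0.142466	0.734326
2	1.059	0.663102	0.247401	0.148498	0.663678
2.04682	1.01279	0.616974	0.242892	0.152927	0.617581
2.16276	0.912741	0.517124	0.23196	0.163657	0.51781
2.28527	0.826033	0.430636	0.220808	0.174588	0.431409
2.41472	0.751699	0.356541	0.20951	0.185649	0.357409
2.5515	0.688752	0.293851	0.198142	0.19676	0.294822
2.69603	0.636251	0.241624	0.186785	0.207842	0.242708
2.84875	0.593356	0.199022	0.17552	0.218814	0.200227
3	0.5612	0.167157	0.165097	0.228946	0.168484
3.01012	0.559361	0.165338	0.164426	0.229598	0.166673
3.18062	0.531521	0.137825	0.153576	0.24012	0.1393
3.36079	0.507654	0.114303	0.143037	0.250314	0.115926
3.55116	0.487396	0.0944052	0.132868	0.260123	0.0961857
3.75232	0.470443	0.0778296	0.123116	0.269497	0.0797771
3.96487	0.456553	0.0643318	0.11382	0.278401	0.0664557
4	0.4546	0.0624431	0.112376	0.279781	0.0645961
4.18946	0.445183	0.0533696	0.105006	0.286807	0.0556794
4.42677	0.435519	0.0441295	0.0966896	0.2947	0.0466348
4.67753	0.427368	0.0364172	0.0888778	0.302073	0.0391278
4.94249	0.420569	0.0300739	0.0815687	0.308927	0.0329997
5	0.4193	0.0289024	0.0800971	0.310301	0.0318747
5.22245	0.414889	0.0248663	0.0747533	0.31527	0.0280177
5.51828	0.410047	0.0205144	0.0684173	0.321116	0.0239018
5.83086	0.405999	0.0169749	0.0625421	0.326482	0.0206091
6	0.4042	0.0154477	0.0596678	0.329084	0.0192146
6.16115	0.402671	0.0141754	0.0571064	0.331389	0.0180679
6.51015	0.39976	0.0118147	0.0520871	0.335858	0.0159771
6.87892	0.397173	0.00980136	0.0474602	0.339912	0.0142457
7.26858	0.394868	0.00809323	0.0432016	0.343573	0.0128323
7.68031	0.3928	0.00664975	0.0392875	0.346863	0.0116965
8	0.3914	0.00572866	0.0365988	0.349073	0.011012
8.11536	0.390935	0.00543534	0.0356949	0.349804	0.0108035
8.57506	0.389294	0.00447555	0.0324015	0.352417	0.0101793
9.06079	0.38783	0.00372417	0.0293862	0.35472	0.00977824
9.57404	0.386463	0.00310289	0.0266288	0.356732	0.00952259
10	0.3854	0.00265336	0.0246203	0.358126	0.00937311
10.1164	0.385117	0.00253763	0.0241104	0.358469	0.00933884
10.6894	0.383817	0.00205534	0.0218128	0.359949	0.00925453
11.2949	0.382578	0.00167305	0.0197193	0.361186	0.0092873
11.9347	0.38138	0.0013722	0.0178138	0.362194	0.00941919
12.6108	0.380201	0.00113456	0.0160814	0.362985	0.00963257
13.3251	0.379023	0.000942152	0.0145081	0.363573	0.00991008
14.0799	0.377825	0.000777297	0.0130807	0.363967	0.0102346
14.8775	0.376589	0.000622581	0.0117871	0.364179	0.0105894
15	0.3764	0.000599361	0.0116052	0.364195	0.0106438
15.7202	0.375323	0.000490694	0.0106157	0.364217	0.0109876
16.6107	0.374059	0.000413358	0.00955609	0.36409	0.0114617
17.5516	0.372773	0.000369701	0.00859828	0.363805	0.0119912
18.5458	0.371441	0.000338268	0.00773322	0.36337	0.0125551
19.5963	0.37004	0.000297963	0.00695249	0.36279	0.013133
20	0.3695	0.000276638	0.00668337	0.36254	0.0133463
20.7063	0.368556	0.000236333	0.00624836	0.362072	0.0137128
21.8793	0.367007	0.000174099	0.00561372	0.361219	0.0143155
23.1186	0.365397	0.000117225	0.00504203	0.360238	0.0149476
24.4282	0.363727	6.93687e-05	0.00452734	0.35913	0.0156129
25.8119	0.361999	3.41739e-05	0.00406418	0.3579	0.0163152
27.274	0.360214	1.52541e-05	0.00364758	0.356551	0.0170584
28.819	0.358375	1.61808e-05	0.00327303	0.355085	0.0178461
30	0.357	3.13795e-05	0.00302411	0.353945	0.0184503
30.4514	0.35648	3.82922e-05	0.00293639	0.353505	0.0186795
32.1763	0.354492	4.64819e-05	0.00263393	0.351811	0.0195235
33.999	0.352407	3.76976e-05	0.00236228	0.350007	0.0203746
35.9249	0.350236	2.52815e-05	0.00211835	0.348092	0.0212459
37.9598	0.347991	2.22704e-05	0.00189937	0.34607	0.0221499
40	0.3458	3.96885e-05	0.00171215	0.344048	0.0230501
40.1101	0.345684	4.12599e-05	0.00170284	0.343939	0.0230986
42.3821	0.343284	5.41427e-05	0.00152649	0.341703	0.0240632
44.7828	0.340774	4.48503e-05	0.00136829	0.339361	0.0250266
47.3196	0.338174	3.24322e-05	0.00122637	0.336915	0.0260068
50	0.3355	3.53268e-05	0.0010991	0.334366	0.0270212
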