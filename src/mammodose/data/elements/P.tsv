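# element P  Z=15  A=30.974  K_edge_keV=2.1455
# analytic reconstruction of photon interaction coefficients; see tools/make_element_tables.py
# E_keV	mu_rho	mu_rho_pe	mu_rho_coh	mu_rho_incoh	muen_rho
1	403.203	397.499	5.69969	0.0039616	397.499
1.05665	292.722	287.032	5.68614	0.00440042	287.032
1.1165	218.688	213.012	5.67113	0.00488516	213.012
1.17974	168.196	162.536	5.65452	0.00541999	162.536
1.24657	133.184	127.542	5.63616	0.00600935	127.542
1.31718	108.543	102.921	5.61587	0.00665788	102.921
1.39179	90.9858	85.3849	5.5935	0.00737043	85.3849
1.47063	78.3653	72.7883	5.56885	0.00815201	72.7884
1.5	74.7513	69.1834	5.55941	0.00845029	69.1834
1.55394	69.2603	63.7095	5.54173	0.00900771	63.7096
1.64196	62.716	57.1942	5.51194	0.00994269	57.1942
1.73497	58.0829	52.5927	5.47927	0.0109621	52.5927
1.83325	54.9085	49.4529	5.44352	0.0120708	49.4529
1.93709	52.8634	47.4457	5.40447	0.0132736	47.4457
2	52.0966	46.7024	5.38022	0.0140161	46.7025
2.04682	51.7023	46.3258	5.3619	0.0145748	46.3259
2.14529	51.2936	45.9551	5.32268	0.0157651	45.9552
2.14571	472.095	466.757	5.32251	0.0157703	450.926
2.16276	471.453	466.122	5.31562	0.0159782	450.437
2.28527	472.554	467.271	5.26544	0.0174872	452.391
2.41472	477.945	472.714	5.21116	0.019104	458.468
2.5515	486.242	481.068	5.15262	0.0208301	467.347
2.69603	495.818	490.705	5.08971	0.022666	477.46
2.84875	504.678	499.632	5.02231	0.0246109	486.868
3	510.176	505.194	4.95488	0.0265345	492.939
3.01012	510.38	505.403	4.95036	0.0266629	493.184
3.18062	509.354	504.451	4.87383	0.0288187	492.909
3.36079	497.506	492.682	4.79274	0.0310741	482.014
3.55116	553.866	549.125	4.70718	0.0334237	537.872
3.75232	606.422	601.769	4.61725	0.035861	590.098
3.96487	606.223	601.662	4.52314	0.0383793	590.619
4	599.807	595.26	4.50769	0.0387895	584.431
4.18946	549.444	544.978	4.42505	0.0409712	535.511
4.42677	473.645	469.278	4.32326	0.0436294	461.564
4.67753	399.7	395.436	4.21806	0.046347	389.284
4.94249	339.526	335.367	4.10978	0.0491176	330.43
5	329.232	325.096	4.08669	0.0497055	320.364
5.22245	294.749	291.118	3.57898	0.0519358	287.062
5.51828	256.806	254.458	2.29314	0.0547974	251.103
5.83086	214.288	213.031	1.1994	0.0576993	210.372
6	195.316	194.255	1.00119	0.0592205	191.9
6.16115	179.292	178.215	1.01629	0.0606396	176.111
6.51015	150.02	148.762	1.19449	0.0636178	147.1
6.87892	125.593	124.055	1.47121	0.0666338	122.744
7.26858	105.388	103.581	1.73791	0.0696883	102.545
7.68031	88.8178	86.8448	1.90016	0.072782	86.023
8	78.5634	76.5831	1.90526	0.0750974	75.8876
8.11536	75.3111	73.3546	1.88057	0.0759154	72.698
8.57506	64.0946	62.3063	1.70926	0.0790879	61.7788
9.06079	54.6172	53.0571	1.47775	0.0822979	52.6324
9.57404	46.5514	45.2081	1.25771	0.085542	44.866
10	41.0197	39.7995	1.13206	0.0881257	39.5115
10.1164	39.6655	38.4694	1.10734	0.088815	38.1943
10.6894	33.7995	32.7081	0.999283	0.0921095	32.4872
11.2949	28.7943	27.7939	0.904937	0.095416	27.6168
11.9347	24.5257	23.6055	0.821464	0.0987229	23.4638
12.6108	20.8868	20.0384	0.746389	0.102017	19.9252
13.3251	17.7854	17.0025	0.677593	0.105283	16.9123
14.0799	15.1423	14.4205	0.613301	0.108505	14.3488
14.8775	12.8898	12.2261	0.552069	0.111666	12.1693
15	12.5841	11.9289	0.543141	0.11213	11.8741
15.7202	10.9664	10.3582	0.493368	0.11475	10.3136
16.6107	9.32274	8.76643	0.438566	0.117742	8.7316
17.5516	7.92395	7.41458	0.388736	0.120626	7.38769
18.5458	6.73788	6.26986	0.344631	0.12339	6.24941
19.5963	5.73546	5.30272	0.30672	0.126022	5.28749
20	5.40574	4.98447	0.294311	0.126961	4.97091
20.7063	4.88771	4.48483	0.274369	0.128514	4.47385
21.8793	4.16349	3.78794	0.244691	0.130859	3.78046
23.1186	3.54667	3.19584	0.217781	0.133051	3.19126
24.4282	3.02339	2.69442	0.193887	0.135089	2.69224
25.8119	2.581	2.2709	0.173129	0.13697	2.27073
27.274	2.20813	1.91392	0.155515	0.138694	1.91544
28.819	1.89468	1.61345	0.140964	0.140263	1.61642
30	1.69851	1.425	0.132203	0.141309	1.42889
30.4514	1.63158	1.36064	0.129257	0.141678	1.36486
32.1763	1.4079	1.14604	0.11892	0.14294	1.15136
33.999	1.21736	0.963974	0.109336	0.14405	0.97028
35.9249	1.05569	0.810264	0.100414	0.145012	0.817463
37.9598	0.918999	0.681096	0.0920768	0.145826	0.689115
40	0.809087	0.577982	0.0846413	0.146464	0.586726
40.1101	0.8038	0.573044	0.0842627	0.146493	0.581825
42.3821	0.706193	0.482441	0.0767352	0.147017	0.491942
44.7828	0.62279	0.405926	0.0694664	0.147397	0.416117
47.3196	0.551318	0.341069	0.0626121	0.147637	0.351926
50	0.489889	0.285874	0.0562779	0.147738	0.297381
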