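cluster	product	from	to
1	NRPS	128373	191397
2	Lantipeptide	191639	228433
3	T3PKS	254893	292628
4	Thiopeptide	338768	374816
5	Lantipeptide	449647	472959
6	Filipins	544798	631900
7	NRPS	632222	683087
8	Phosphonate	752764	792909
9	NRPS	814767	848264
10	Terpene	1079383	1094356
11	Sceliphrolactam	1237686	1312223
12	NRPS	1368633	1383668
13	NRPS-T1PKS	1460470	1474512
14	Bacteriocin	1544288	1554571
15	Terpene	1588034	1600491
16	NRPS-T1PKS	1646863	1698126
17	Terpene	1714938	1736137
18	Bacteriocin	2135476	2146348
19	Siderophore	2170308	2196218
20	T3 PKS-Terpene	2196485	2241910
21	Ectoine	2365889	2376287
22	Lantipeptide	2829683	2850624
23	Melanin	3125189	3133324
24	T2 PKS	4226586	4269086
25	Lassopeptide	4476131	4497579
26	T3 PKS	4624864	4667988
27	Lantipeptide	4985954	5012231
28	Melanin	5634528	5639110
29	Siderophore	5999342	6017297
30	NRPS	6504488	6559786
31	Prodiginine	6670408	6706365
32	Terpene	6734497	6758278
33	T1 PKS-Terpene	6779444	6838577
34	NRPS	6838626	6874184
35	Lantipeptide	6948157	6973315
36	PKS/FAS	7169469	7244251
37	Factumycin	7248671	7339459
38	Lassopeptide	7363591	7384450
39	Terpene	7568556	7585720
40	NRPS	7611812	7663138
41	Lantipeptide	7695774	7723406
42	T1 PKS-Terpene	7805055	7854201
43	NRPS-T1 PKS	7997743	8031379
44	NRPS	8083462	8121926
45	γ-Butyrolactone	8125632	8127719
46	PKS/FAS	8128024	8185901
47	Terpene	8251315	8271035
48	Terpene	8274362	8305247
49	PKS/FAS	8312476	8367627
50	Unknown	8409881	8446192
51	PKS/FAS	8465511	8538072
52	Lantipeptide	8549285	8564374
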