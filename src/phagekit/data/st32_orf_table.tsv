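orf_id	strand	start	end	size_aa	mw_kda	pi	sd_context	start_codon	predicted_function	hit_subject	hit_identical	hit_smallest	hit_pct	hit_aligned_len
1	+	673	2613	646	72.7	6.09	TGGAGACttacaa	ATG	RNA polymerase	gp01 phiEcoM-GJ1	598	646	93	648
2	+	2640	2846	68	7.89	4.51	AGGATGGcattag	TTG		gp02 phiEcoM-GJ1	48	55	87	55
3	+	3959	4177	72	4.14	8.15	AGGAGAAtaaa	ATG		hypothetical KP8	23	73	32	71
4	+	4217	4453	78	8.9	9.63	CGGAGAGcagaa	ATG		gp04 phiEcoM-GJ1	49	76	64	76
5	+	4456	4644	62	7.5	4.53	ACGAGGTtaatc	ATG		gp05 phiEcoM-GJ1	61	62	98	62
6	+	4641	4835	64	7.3	9.7	TGGAGGCcaa	ATG
7	+	4832	5077	81	9.4	4.32	AGGCGGGttggtt	GTG
8	+	5087	5260	57	6.7	9.25	AGGAGTAttaa	ATG		gp07 phiEcoM-GJ1	56	57	98	57
9	+	5356	5667	103	11.6	4.5	AGGTAATtaa	ATG		gp08 phiEcoM-GJ1	84	99	85	99
10	+	5683	5943	86	9.7	5.6	GGGAGTTatt	ATG		gp09 phiEcoM-GJ1	79	86	92	87
11	+	5936	6118	60	6.4	4.64	TGGGAGTtctgtacc	ATG
12	+	6121	6348	75	8.4	5.24	AGGATAAtc	ATG		gp10 phiEcoM-GJ1	67	75	89	75
13	+	6345	6575	76	8.6	9.58	ACAAGGTttattgca	ATG		gp11 phiEcoM-GJ1	42	68	62	68
14	+	6639	6929	96	10.7	9.47	TGGAGCAttt	ATG		gp12 phiEcoM-GJ1	87	96	91	96
15	+	6922	7155	77	8.8	5.22	AGAAGGTgaagc	GTG		gp13 phiEcoM-GJ1	68	77	88	77
16	+	7152	7439	95	10.8	9.3	TGGAGAAattaaagca	ATG		gp14 phiEcoM-GJ1	84	95	88	95
17	+	7439	7636	65	7.82	9.81	AGGTGATgta	ATG		IME11_76	29	65	45	68
18	+	7715	8197	160	18.8	8.79	TGGAGGGctt	ATG		CBB_348	72	160	45	161
19	+	8323	8700	125	14.2	5.78	AAGAGAAtcttaatc	ATG	ssDNA-binding protein	gp15 phiEcoM-GJ1	96	125	77	126
20	+	8823	9719	298	33.2	7.74	GTGAGGAatatc	ATG		gp17 phiEcoM-GJ1	159	229	69	229
21	+	9775	10125	116	13.1	6.07	CGGAGCAttt	ATG		gp18 phiEcoM-GJ1	114	116	98	116
22	+	10122	10355	77	8.72	5.29	AGGAAGTtaa	ATG		gp19 phiEcoM-GJ1	56	77	73	77
23	+	10345	10614	89	10.3	4.7	AGGAAATccattcc	GTG
24	+	10607	11023	138	15.7	9.48	AGGAGCTgaaaa	ATG	endolysin	gp21 phiEcoM-GJ1	110	131	84	131
25	+	11044	11322	92	10.9	5.7	TGGAGCAtccg	ATG
26	+	11309	11857	182	21.2	4.03	GGGAGAAactca	ATG	antirestriction protein	gp22 phiEcoM-GJ1	145	181	80	181
27	+	11850	12089	79	9.2	6.9	CGAAGGGatactattctcaa	ATG		gp23 phiEcoM-GJ1	73	79	92	79
28	+	13092	13295	67	7.5	4.58	TGGAGAGttcct	ATG		gp25 phiEcoM-GJ1	57	67	85	69
29	+	13292	13582	96	11.3	9.1	AGGAGCTgcaaaa	ATG
30	+	13579	13869	96	10.6	5.25	CGGAGTTccatt	TTG		gp27 phiEcoM-GJ1	93	96	97	97
31	+	13872	14546	224	25.9	8.28	ACAAGGCcactaaaa	ATG		gp28 phiEcoM-GJ1	223	224	99	224
32	+	14670	15008	112	12.3	4.47	ATAAGGTatatacaa	ATG		gp29 phiEcoM-GJ1	111	112	99	112
33	+	15395	15532	45	5.1	8.99	CGGAGCAataattaat	TTG
34	+	15547	15789	80	8.8	9.24	AGAAGCTatgccaat	GTG		gp30 phiEcoM-GJ1	77	80	96	80
35	+	16029	16169	46	4.8	3.76	TGGAGTCctc	ATG
36	+	16178	16414	78	8.5	9.05	AGGTGATtt	ATG		gp31 phiEcoM-GJ1	77	78	99	78
37	+	17404	17634	76	8.5	4.89	TGGAGAGaaac	ATG		gp32 phiEcoM-GJ1	74	76	97	76
38	+	17691	18341	216	24.8	5.99	CGGAGAGcaa	ATG	thymidylate synthase	gp33 phiEcoM-GJ1	196	216	91	216
39	+	18346	20109	587	66	5.95	ACCAGGAataaataa	ATG	helicase/primase	gp35 phiEcoM-GJ1	560	587	95	587
40	+	20175	22109	644	74.6	6.41	TGGAGCCatact	GTG	DNA polymerase	gp37 phiEcoM-GJ1	637	644	99	644
41	+	22109	22381	90	10.1	4.37	CAGAGATtcacta	ATG		gp38 phiEcoM-GJ1	86	90	96	90
42	+	22412	23278	288	31	4.86	AGGTACTcaaa	ATG		gp39 phiEcoM-GJ1	288	288	100	288
43	+	23312	24349	345	39.4	8.09	GGGAGCCtttaatt	TTG	exonuclease	gp40 phiEcoM-GJ1	342	345	99	345
44	+	24361	24885	174	20.1	9.46	TGGAGTTgga	ATG		gp41 phiEcoM-GJ1	173	174	99	174
45	+	24875	25630	251	28.5	8.64	AGAAAGAatctta	ATG	DNA ligase	gp42 phiEcoM-GJ1	233	251	93	251
46	+	25623	26249	208	23.5	6.38	GTGAGGAaagtt	TTG		gp43 phiEcoM-GJ1	203	208	98	208
47	+	26252	26839	195	20.7	6.66	ATCAAGTagagaaataatc	ATG	deoxyuridine 5'-triphosphate nucleotidylhydrolase	gp44 phiEcoM-GJ1	164	195	82	199
48	+	26858	27064	68	8.2	4.32	TGGAGCAtcc	ATG		PP74_27	37	68	54	73
49	+	27082	27411	109	12.2	9.7	TGGAACCtatctgaa	ATG		gp45 phiEcoM-GJ1	109	109	100	109
50	+	27467	27652	61	7	4.4	CGGAGTCgctt	ATG		gp46 phiEcoM-GJ1	61	61	100	61
51	+	27672	29690	672	76	6.02	AAGAGAAcgaatca	ATG	large subunit terminase	gp48 phiEcoM-GJ1	667	671	99	671
52	+	29693	29905	70	7.9	9.18	TGGATGTaaat	ATG		gp49 phiEcoM-GJ1	70	70	100	70
53	+	29905	31221	438	49.1	8.16	AGGAAGAaata	ATG	portal protein	gp50 phiEcoM-GJ1	434	438	99	438
54	+	31190	32254	354	39	4.8	AAAGGGTaacgcaa	GTG		gp51 phiEcoM-GJ1	353	354	99	354
55	+	32264	32737	157	16.4	6.26	ATAAGGTaagaca	ATG		gp52 phiEcoM-GJ1	147	157	94	157
56	+	32818	33030	70	7.3	6.06	TGTAACT	GTG		gp67 vB_EamM-Y2	51	70	73	90
57	+	33086	34093	335	36.7	5.17	TGGATTAaattac	ATG	major capsid protein	gp53 phiEcoM-GJ1	323	335	96	335
58	+	34140	34580	146	16.1	5.34	AAGAGAAatagta	ATG		gp54 phiEcoM-GJ1	116	146	79	146
59	+	34581	34970	129	14.6	4.48	AGTTGGCgtaa	ATG		gp55 phiEcoM-GJ1	124	129	96	129
60	+	34967	35329	120	13.9	9.16	GGGTCACagtt	TTG		gp56 phiEcoM-GJ1	120	120	100	120
61	+	35326	35838	170	19.3	4.98	AGGAGTTagagaa	ATG		gp57 phiEcoM-GJ1	167	170	98	170
62	+	35839	37287	482	50.9	4.75	AGGGAATctaa	ATG		gp58 phiEcoM-GJ1	447	482	93	482
63	+	37298	37753	151	16.5	6.55	AGGTGCGataa	GTG		gp59 phiEcoM-GJ1	148	151	98	151
64	+	37765	38223	152	17.3	5.1	AGTAAGT	ATG		gp60 phiEcoM-GJ1	152	152	100	152
65	+	38229	38399	56	6.7	4.67	CGGAGACagtttagtatcc	ATG		gp61 phiEcoM-GJ1	55	56	98	73
66	+	38383	42108	1241	134.6	5.36	AGAAACTcgaaccagtag	ATG	tail fiber	gp62 phiEcoM-GJ1	946	1239	76	1239
67	+	42182	43291	369	40.7	5.13	AATAGGTatatcgca	ATG		gp63 phiEcoM-GJ1	366	369	99	369
68	+	43291	44178	295	31.2	5.98	TGGAGTCatttta	ATG		gp64 phiEcoM-GJ1	295	295	100	295
69	+	44175	44537	120	13.7	5.07	GGGACGTatcct	ATG		gp65 phiEcoM-GJ1	120	120	100	120
70	+	44530	45324	264	28.2	5.8	AGAGTGTacttgaac	GTG	baseplate assembly protein	gp66 phiEcoM-GJ1	263	264	99	264
71	+	45324	45695	123	13.5	5.22	ATGAAATa	ATG		gp67 phiEcoM-GJ1	117	123	95	123
72	+	45671	46828	385	41.2	4.55	CGGAATTcttaac	ATG		gp68 phiEcoM-GJ1	361	385	94	385
73	+	46830	47471	213	23.5	5.82	CAGATGTgacagtataat	ATG		gp69 phiEcoM-GJ1	193	213	91	213
74	+	47471	48619	382	42.3	5.49	CGGAGAAata	ATG		gp70 phiEcoM-GJ1	342	382	90	382
75	+	48619	50016	465	50.2	8.17	AGGCCATa	ATG		gp71 phiEcoM-GJ1	314	465	68	465
76	+	50025	51071	348	36.3	6.6	AGGATTCaaa	ATG	tail fiber protein	gp72 phiEcoM-GJ1	250	348	72	356
77	+	51079	51420	113	12.3	7.95	AGGAACTc	ATG	holin	gp73 phiEcoM-GJ1	110	113	97	113
78	+	51438	51992	184	20.7	9.57	AGGAACTcga	ATG	endolysin	gp74 phiEcoM-GJ1	178	184	97	184
79	+	51992	53092	366	42.2	4.76	AGGAAATctgta	ATG	ribonucleotide reductase beta subunit	gp75 phiEcoM-GJ1	340	366	93	372
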