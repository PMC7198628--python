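group	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Annelida	34	70747	31	184790	17	14337	3	95	5	1438	68	271407
Arthropoda	133	700309	154	1416897	316	1465985	87	488705	123	549241	624	4621137
Bryozoa	1	10	0	0	0	0	2	498	0	0	2	508
Chordata	0	0	1	40	3	131	1	9	1	4	4	184
Cnidaria	5	1181	13	31041	2	310	1	12	1	8	18	32552
Echinodermata	0	0	1	55	0	0	0	0	0	0	1	55
Gastrotricha	3	1439	1	592	7	8138	10	81062	4	9654	16	100885
Kinorhyncha	3	4241	2	4131	2	321	0	0	1	59	5	8752
Mollusca	3	120	6	668	0	0	2	2939	1	5	9	3732
Nematoda	194	454408	158	613752	126	272220	145	751010	113	299857	496	2391247
Nemertea	0	0	2	608	1	79	0	0	0	0	2	687
Platyhelminthes	60	44008	43	27391	73	372749	82	441294	78	602164	228	1487606
Porifera	1	18	1	46	0	0	0	0	0	0	2	64
Rotifera	1	16	3	110	2	82	3	148	2	696	8	1052
Tardigrada	0	0	0	0	1	2	2	50	1	38	3	90
Xenacoelomorpha	15	57360	17	58794	19	35249	7	1790	5	3804	37	156997
Unknown	12	3559	19	235	50	2273	28	2361	23	1458	116	9886
Total	465	1337416	452	2339150	619	2171876	373	1769973	358	1468426	1639	9086841
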