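group	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Annelida	5	1119	7	7467	1	157	1	382	3	808	13	9933
Arthropoda	71	100897	96	98117	32	1204537	53	72619	86	754285	265	2230455
Bryozoa	1	45	1	68	0	0	0	0	0	0	1	113
Chordata	0	0	2	16	0	0	1	807	0	0	3	823
Cnidaria	6	280	3	498	0	0	1	717	0	0	8	1495
Echinodermata	1	34	1	44	0	0	0	0	0	0	1	78
Gastrotricha	2	576	3	800	0	0	0	0	0	0	3	1376
Mollusca	6	173	17	39808	14	241184	16	8113	25	63903	57	353181
Nematoda	17	2366	35	17031	5	886	45	507414	39	63713	106	591410
Nemertea	1	81	2	123	0	0	0	0	0	0	2	204
Onychophora	1	45	0	0	0	0	0	0	1	15	2	60
Platyhelminthes	5	471	4	7888	22	70161	32	321833	44	1139563	82	1539916
Porifera	2	149	1	730	0	0	1	11	0	0	3	890
Rotifera	0	0	2	32	0	0	1	438	0	0	3	470
Xenacoelomorpha	5	4866	13	88069	6	19537	3	1523	8	16178	25	130173
Unknown	38	914920	44	2403064	14	9431	43	40295	42	33607	134	3401317
Total	161	1026022	231	2663755	94	1545893	197	954152	248	2072072	708	8261894
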