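group	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Amoebozoa	1	2	6	124	0	0	19	998	1	2	27	1126
Archaeplastida	30	44634	35	29557	22	4583	45	43967	24	2415	105	125156
Excavata	0	0	2	22	0	0	4	1396	1	11	6	1429
SAR	201	23514	470	41770	214	51354	549	202797	269	68025	1313	387460
Other Eukaryote	6	409	16	682	23	2927	43	2581	32	1205	92	7804
Metazoa	465	1337416	452	2339150	619	2171876	373	1769973	358	1468426	1639	9086841
Fungi	20	11245	31	458	38	6056	87	50992	35	1690	168	70441
Other Opisthokonta	1	4	7	115	4	57	7	116	2	15	18	307
Unknown	26	1339	83	2778	26	1511	105	3551	27	1680	247	10859
Total	750	1418563	1102	2414656	946	2238364	1232	2076371	749	1543469	3615	9691423
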