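group	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Amoebozoa	16	7819	28	2111	11	1434	20	6587	45	71496	88	89447
Archaeplastida	14	969	21	2008	3	5437	10	3908	12	9621	46	21943
Excavata	1	67	1	254	0	0	0	0	0	0	1	321
SAR	60	10085	106	19381	10	3564	12	1312	41	7428	185	41770
Other Eukaryote	69	8516	104	18510	122	5430	32	5453	44	22356	202	60265
Metazoa	161	1026022	231	2663755	94	1545893	248	2072072	197	954152	708	8261894
Fungi	1	39	4	59	0	0	5	2281	6	221	13	2600
Other Opisthokonta	13	584	21	3210	6	11218	9	1258	57	9562	94	25832
Unknown	137	20211	346	233221	134	79906	134	30889	295	174901	939	539128
Total	472	1074312	862	2942509	280	1652882	470	2123760	697	1249737	2276	9043200
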