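higher_group	taxon	rank	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Acoela	Archaphanastoma agile	species	2	1676	7	56506	0	0	0	0	0	0	7	58182
Acoela	Archaphanastoma macrospiriferum	species	0	0	0	0	1	5	0	0	3	37	3	42
Acoela	Archaphanastoma ylvae	species	0	0	1	12	5	19532	1	503	1	8	5	20055
Acoela	Paedomecynostomum bruneum	species	0	0	0	0	0	0	1	1017	3	16104	3	17121
Acoela	Philactinoposthia sp. 3	species	0	0	2	201	0	0	0	0	0	0	2	201
Acoela	Philactinoposthia	genus	1	3090	2	31277	0	0	1	3	1	29	3	34399
Acoela	Mecynostomidae	family	1	93	1	73	0	0	0	0	0	0	1	166
Acoela	Acoela	higher	1	7	0	0	0	0	0	0	0	0	1	7
Macrostomorpha	Bradynectes sterreri	species	0	0	0	0	0	0	1	14	0	0	1	14
Macrostomorpha	Microstomidae	family	0	0	0	0	0	0	1	8	0	0	1	8
Rhabdocoela	Austrorhynchus pacificus	species	1	8	1	13	13	18126	13	28311	11	62680	28	109138
Rhabdocoela	Carcharodorhynchus sp. 24	species	0	0	0	0	0	0	0	0	1	35	1	35
Gastrotricha	Chaetonotida	higher	2	576	2	794	0	0	0	0	0	0	2	1370
Gastrotricha	Gastrotricha	higher	0	0	1	6	0	0	0	0	0	0	1	6
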