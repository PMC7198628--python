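higher_group	taxon	rank	Tjarno_otus	Tjarno_reads	Fiskebackskil_otus	Fiskebackskil_reads	Halmstad_otus	Halmstad_reads	Kaseberga_otus	Kaseberga_reads	Landon_otus	Landon_reads	total_otus	total_reads
Acoela	Actinoposthia sp. 8	species	0	0	0	0	1	7	0	0	0	0	1	7
Acoela	Anaperus tvaerminnensis	species	0	0	2	33	1	5190	1	20	1	30	2	5273
Acoela	Aphanostoma sp. AWHel19	species	1	576	0	0	0	0	0	0	0	0	1	576
Acoela	Archaphanostoma agile	species	4	27639	5	22978	1	466	1	20	0	0	7	51103
Acoela	Archaphanostoma macrospiriferum	species	1	1772	1	688	9	24026	1	1615	1	3711	9	31812
Acoela	Archaphanostoma ylvae	species	0	0	0	0	3	4483	1	39	1	43	3	4565
Acoela	Archaphanostoma fontaneti	species	1	242	1	346	0	0	0	0	0	0	1	588
Acoela	Eumecynostomum macrobursalium	species	2	25304	2	29170	1	945	1	16	0	0	2	55435
Acoela	Isodiametra sp. 2	species	1	92	1	1497	0	0	0	0	0	0	1	1589
Acoela	Mecynostomum auritum	species	1	68	1	97	1	10	0	0	0	0	1	175
Acoela	Mecynostomum lutheri	species	2	683	2	1947	1	43	0	0	0	0	2	2673
Acoela	Paramecynostomum sp. UJ0853	species	1	10	0	0	0	0	0	0	0	0	1	10
Acoela	Paraproporus sp. 3	species	0	0	0	0	0	0	0	0	1	10	1	10
Acoela	Paratomella unichaeta	species	0	0	0	0	1	79	0	0	1	10	1	89
Acoela	Philactinoposthia sp. 3	species	1	974	2	2038	0	0	0	0	0	0	2	3012
Acoela	Archaphanostoma	genus	0	0	0	0	0	0	1	5	0	0	1	5
Acoela	Mecynostomum	genus	0	0	0	0	0	0	1	75	0	0	1	75
Macrostomorpha	Dolichomacrostomum uniporum	species	1	1160	0	0	1	23356	1	5886	1	7690	1	38092
Macrostomorpha	Microstomum crildensis	species	2	906	1	1663	0	0	1	1495	0	0	2	4064
Macrostomorpha	Psammomacrostomum sp. 1	species	0	0	0	0	1	1142	1	52	1	496	1	1690
Macrostomorpha	Macrostomum	genus	0	0	1	318	0	0	0	0	0	0	1	318
Macrostomorpha	Microstomum	genus	3	3467	6	5539	2	168	1	912	0	0	7	10086
Macrostomorpha	Dolichomacrostomidae	family	0	0	0	0	0	0	0	0	1	5	1	5
Macrostomorpha	Macrostomorpha	higher	0	0	0	0	0	0	1	39	0	0	1	39
Rhabdocoela	Brinkmanniella palmata	species	1	90	4	264	0	0	0	0	0	0	4	354
Rhabdocoela	Cheliplana orthocirra	species	1	2182	1	6	1	5018	1	21891	4	63315	4	92412
Rhabdocoela	Cicerina tetradactyla	species	4	6419	1	29	5	29307	2	41527	4	86616	9	163898
Rhabdocoela	Diascorhynchus serpens	species	1	2469	0	0	1	243	2	7823	3	9383	4	19918
Rhabdocoela	Gnathorhynchus inermis	species	1	1240	0	0	3	5823	1	5471	2	21330	4	33864
Rhabdocoela	Litucivis serpens	species	0	0	0	0	0	0	0	0	1	1429	1	1429
Rhabdocoela	Odontorhynchus aculeatus	species	0	0	1	21	0	0	0	0	0	0	1	21
Rhabdocoela	Paracicerina laboeica	species	2	4058	0	0	4	63699	1	25718	1	30001	5	123476
Rhabdocoela	Paracrorhynchus sp. TJ2014	species	1	287	0	0	0	0	0	0	0	0	1	287
Rhabdocoela	Placorhynchus dimorphis	species	1	141	0	0	0	0	1	1392	0	0	2	1533
Rhabdocoela	Placorhynchus octaculeatus	species	2	751	1	10	3	480	6	41174	2	590	10	43005
Rhabdocoela	Prognathorhynchus busheki	species	1	830	2	2011	1	446	0	0	0	0	2	3287
Rhabdocoela	Proxenetes quinquespinosus	species	2	793	1	694	1	640	0	0	0	0	2	2127
Rhabdocoela	Psammorhynchus tubulipenis	species	2	314	0	0	0	0	0	0	0	0	2	314
Rhabdocoela	Ptychopera westbladi	species	0	0	1	15	0	0	0	0	0	0	1	15
Rhabdocoela	Schizorhynchoides caniculatus	species	3	2407	2	55	9	72324	3	7928	12	114977	19	197691
Rhabdocoela	Thylacorhynchus ambronensis	species	1	162	0	0	3	5685	0	0	1	1509	3	7356
Rhabdocoela	Uncinorhynchus flavidus	species	1	223	1	372	0	0	1	214	0	0	2	809
Rhabdocoela	Zonorhynchus seminascatus	species	2	50	2	63	0	0	0	0	0	0	2	113
Rhabdocoela	Ceratopera	genus	0	0	0	0	0	0	1	3622	0	0	1	3622
Rhabdocoela	Cheliplana	genus	2	194	0	0	2	1330	1	10	5	13949	8	15483
Rhabdocoela	Gnathorhynchus	genus	1	152	0	0	1	456	1	99	2	2021	2	2728
Rhabdocoela	Pogaina	genus	1	68	1	27	0	0	0	0	0	0	1	95
Rhabdocoela	Proxenetes	genus	2	1672	2	2091	0	0	0	0	0	0	3	3763
Rhabdocoela	Thylacorhynchus	genus	0	0	0	0	2	3732	2	304	3	2098	5	6134
Rhabdocoela	Toia	genus	1	6	1	832	0	0	0	0	0	0	1	838
Rhabdocoela	Cicerininae	family	2	11	0	0	4	17	5	34	3	1041	13	1103
Rhabdocoela	Gnathorhynchidae	family	1	304	1	1264	0	0	0	0	0	0	1	1568
Rhabdocoela	Promesostomidae	family	0	0	0	0	2	311	3	950	3	10079	3	11340
Rhabdocoela	Schizorhynchidae	family	0	0	0	0	2	13	0	0	2	49	4	62
Rhabdocoela	Schizorhynchia	higher	0	0	0	0	1	3	0	0	1	3	2	6
Rhabdocoela	Thalassotyphloplanida	higher	3	268	3	350	0	0	0	0	2	11	8	629
Rhabdocoela	Eukalyptorhynchia	higher	1	105	0	0	0	0	3	3636	1	37	4	3778
Rhabdocoela	Neodalyellida	higher	0	0	0	0	1	244	0	0	0	0	1	244
Rhabdocoela	Dalytyphloplanida	higher	1	366	1	386	0	0	0	0	0	0	1	752
Rhabdocoela	Kalyptorhynchia	higher	1	27	0	0	0	0	0	0	0	0	1	27
Rhabdocoela	Rhabdocoela	higher	1	21	1	236	1	103	0	0	0	0	4	360
Gastrotricha	Macrodasys sp2	species	1	362	1	592	0	0	0	0	0	0	1	954
Gastrotricha	Halichaetonotus paradoxus	species	0	0	0	0	1	911	1	375	0	0	1	1286
Gastrotricha	Turbanella cornuta	species	2	1077	0	0	3	6495	5	79970	1	8684	8	96226
Gastrotricha	Chaetonotus	genus	0	0	0	0	0	0	0	0	1	2	1	2
Gastrotricha	Halichaetonotus	genus	0	0	0	0	1	499	2	47	1	268	2	814
Gastrotricha	Paraturbanella	genus	0	0	0	0	0	0	1	10	0	0	1	10
Gastrotricha	Turbanellidae	family	0	0	0	0	1	3	0	0	0	0	1	3
Gastrotricha	Chaetonotida	higher	0	0	0	0	1	230	1	660	1	700	1	1590
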