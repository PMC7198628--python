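marker	site	input	filtered_denoised	merged	non_chimeric	otus
18S	Tjarno	5837687	2071031	1947662	1418563	750
18S	Fiskebackskil	12355933	4086192	3428908	2414656	1102
18S	Halmstad	7751818	2861465	2716815	2238364	946
18S	Kaseberga	8978859	3378949	3094138	2076371	1232
18S	Landon	6486137	2447217	2273099	1543469	749
18S	TOTAL	41410434	14844854	13460622	9691423	3615
COI	Tjarno	2574531	1202237	1118651	1076404	570
COI	Fiskebackskil	6379738	3130397	3019902	2946301	1172
COI	Halmstad	3557580	1780771	1754494	1654651	350
COI	Kaseberga	3162540	1474187	1445150	1254788	958
COI	Landon	4810016	2350865	2303991	2125578	616
COI	TOTAL	20484405	9938457	9642188	9057722	2482
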