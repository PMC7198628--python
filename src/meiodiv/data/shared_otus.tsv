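marker	otu_id	super_assemblage	phylum	every_sample
18S	90f6a60093b3fdc85ba7a1cb35057073	Archaeplastida		0
18S	bed5cab4de8b0238d337199cbcbee51e	Archaeplastida		0
18S	fdbc082988924f7c1ecd32c8949fc3c1	Archaeplastida		0
18S	22fa8218e35977d76ebdb9aeb305ac6a	Fungi		0
18S	b04cc75c142fdc390a9737cba8b3016e	Fungi		0
18S	eec420685696d90a0d07d87d1110ab7f	Metazoa	Annelida	0
18S	4cc10b4ef5359220090acc37ec45e2c8	Metazoa	Arthropoda	1
18S	5279f7673b35821491c9532851458765	Metazoa	Arthropoda	0
18S	86fb00a9f505e8b809054f2b77be9c0f	Metazoa	Arthropoda	0
18S	c1f41b8fe6a03d71ad363664c628eba3	Metazoa	Arthropoda	0
18S	d3a2d62586eef235d87bf5ea32a69eba	Metazoa	Arthropoda	0
18S	dc820b776904fb714527a25dd072bf30	Metazoa	Arthropoda	0
18S	e8a53be7443a9c3919d5a70bc01c4e33	Metazoa	Arthropoda	0
18S	e92edef507628b3d47afa8f055b42c8d	Metazoa	Arthropoda	0
18S	1c33f41b42787bd44f84b7928948c040	Metazoa	Nematoda	0
18S	39cbb16486c7a5fd5226e28238c4f361	Metazoa	Nematoda	0
18S	3d4364653ddb334a4bd6808b5cb1cddb	Metazoa	Nematoda	0
18S	5efaede8aefab69c9471fb10ae896a26	Metazoa	Nematoda	1
18S	6308c0b4f2b682e85b3fcceec379c115	Metazoa	Nematoda	0
18S	7ad85c5748dc0f24ff0d0cf699142c8a	Metazoa	Nematoda	0
18S	845b4bc23a0b60a614338ad5e16752e2	Metazoa	Nematoda	0
18S	a3647b4367700bb20211a2a8c9c6d15f	Metazoa	Nematoda	0
18S	bd7d86e4c48f271d2b12f3ebe73a6e0a	Metazoa	Nematoda	0
18S	bfc135032b34820cc5dcaa27fcb5d7a0	Metazoa	Nematoda	0
18S	ea4de89257c0302aa7191d662ac8ca44	Metazoa	Nematoda	0
18S	1ec64309427bdf249f924851356d587f	Metazoa	Platyhelminthes	0
18S	25726baf15005d4fc2d1e47eb24465db	Metazoa	Platyhelminthes	0
18S	525ec3abad4bf5a6324c56330686504f	Metazoa	Platyhelminthes	0
18S	c741c7c5a6e916d37a4bf47635bf293d	Metazoa	Platyhelminthes	0
18S	dcb254e4577a5beff4921ca44fc3533e	Metazoa	Platyhelminthes	0
18S	e41276741e18d4b131ed89b4e11b6285	Metazoa	Platyhelminthes	0
18S	e875782ac3f5d26eaa6956dd4cc35685	Metazoa	Platyhelminthes	0
18S	1d5357d35317460eb71604b44982a32b	Metazoa	Xenacoelomorpha	0
18S	0bd8922559eed4098d5ac4a255ba7871	SAR		0
18S	64e1b3fa6bbd727a7ef9a9a3cd9eda42	SAR		0
18S	9e872c52ece55247a0a784b494fd3fd6	SAR		0
18S	ebd50793368d8f06efadf1e41e92c178	SAR		0
COI	aee5e5584a107329178954de96480088	Metazoa	Arthropoda	0
COI	c091b08c6c169ead97f32db984eb9fe8	Metazoa	Arthropoda	0
COI	c44fd006d45976d3eca583816e631c4d	Metazoa	Arthropoda	0
COI	cc05db8802aad5d02e18dd1f2780ed6c	Metazoa	Arthropoda	0
COI	ff8981ce44e0943f8f2fe599e0c7af20	Metazoa	Arthropoda	0
COI	f660505d1d7e488403938eb904f64535	Metazoa	Mollusca	0
COI	17f8cd824b6985c53286f7fa0045669c	Metazoa	Platyhelminthes	1
COI	ee6c3481fe8b621d9a9ab8975fbb7418	Metazoa	Platyhelminthes	0
COI	3059851980624611c4b991bf0271ec64	UNKNOWN		0
COI	0b5b6eeeeaeda4b023588ad575c77045	UNKNOWN		0
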