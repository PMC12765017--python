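sample	gene	hgvsp	pipeline	pathways	detection_sources	breed
TC1020	MSH3	M282R	RNA	MMR	rna;wes_tumor;wes_normal	Beagle
TC1241	SIRT6	R145H	RNA	BER,DSBR	rna;wes_tumor;wes_normal	Border Collie
TC67	KAT5	I531L	RNA	DSBR	rna;wes_tumor;wes_normal	Dachshund
TC2402	NSD2	A1309T	RNA	DSBR	rna;wes_tumor;wes_normal	Labrador Retriever
TC1123	MLH3	S1103Y	RNA	MMR	rna;wes_tumor;wes_normal	Malamute
TC1088	NEIL1	W296*	RNA	BER	rna;wes_tumor;wes_normal	Mix
TC1088	TIMELESS	Q1283*	RNA	DSBR	rna;wes_tumor;wes_normal	Mix
TC538	POLQ	R793*	RNA	BER,DSBR	rna;wes_tumor;wes_normal	Mix
TC1164	MDC1	R1649Q	RNA	DSBR	rna;wes_tumor;wes_normal	Mix
TC1473	ERCC4	H201Q	RNA	DSBR,NER	rna;wes_tumor;wes_normal	Mix
TC2288	MCM9	R450K	RNA	MMR	rna;wes_tumor;wes_normal	Mix
TC22	MUTYH	R658W	WES	BER,MMR	rna;wes_tumor	Beagle
TC22	MSH6	R990H	WES	MMR	wes_tumor	Beagle
TC22	MSH6	E998D	WES	MMR	wes_tumor	Beagle
TC2110	DCLRE1C	G207Efs*20	WES	DSBR	rna;wes_tumor	Labrador Retriever
TC2089	BARD1	Q542del	WES	DSBR	wes_tumor	Labrador Retriever
TC1123	BARD1	L654F	WES	DSBR	wes_tumor	Malamute
TC538	MUS81	H375N	WES	DSBR	wes_tumor	Mix
TC2288	ACD	V266I	WES	BER	wes_tumor	Mix
TC67	POLD3	A362Sfs*5	RNA	BER,DSBR,MMR,NER	rna	Dachshund
TC902	POT1	M711L	RNA	BER	rna	German Shepherd
TC2402	RIF1	I2399L	RNA	DSBR	rna	Labrador Retriever
TC627	ATM	K687Q	RNA	DSBR	rna	Labrador Retriever
TC2289	MRE11	L286V	RNA	DSBR	rna	Labrador Retriever
TC1593	TP53	I247L	RNA	DSBR,NER	rna	Portuguese Water Dog
TC2011	LIG1	S444R	RNA	BER,MMR	rna	Shetland Sheepdog
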