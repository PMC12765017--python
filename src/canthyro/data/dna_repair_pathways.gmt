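MMR	mismatch repair	MSH3	MLH3	MCM9	MUTYH	MSH6	POLD3	LIG1
BER	base excision repair	SIRT6	NEIL1	POLQ	MUTYH	ACD	POLD3	POT1	LIG1
NER	nucleotide excision repair	ERCC4	POLD3	TP53
DSBR	double-strand break repair	SIRT6	KAT5	NSD2	TIMELESS	POLQ	MDC1	ERCC4	DCLRE1C	BARD1	MUS81	POLD3	RIF1	ATM	MRE11	TP53
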