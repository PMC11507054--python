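EMT	minimal epithelial-mesenchymal transition marker panel; supply your preferred signature (e.g. the hallmark EMT set) for real analyses	VIM	FN1	CDH2	SNAI1	SNAI2	TWIST1	ZEB1	ZEB2	MMP2	MMP9	SPARC	COL1A1
S	minimal S-phase marker panel	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	PCNA	RRM1	RRM2	CDC6
G2M	minimal G2M-phase marker panel	MKI67	TOP2A	CCNB1	CCNB2	CDK1	AURKA	AURKB	BUB1	PLK1	UBE2C
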