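# demo CTD-style chemical-gene interaction export (synthetic excerpt)
ChemicalName	CasRN	GeneSymbol	InteractionActions
Curcumin	458-37-7	CFTR	decreases^activity
Curcumin	458-37-7	HSP90AA1	decreases^expression
Curcumin	458-37-7	NFKB1	decreases^activity
Ivacaftor	873054-44-5	CFTR	increases^activity
Geldanamycin	30562-34-6	HSP90AA1	decreases^activity
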