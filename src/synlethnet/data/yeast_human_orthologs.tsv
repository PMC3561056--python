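yeast	human
BRE1	RNF20
CDC4	FBXW7
CTF18	CHTF18
CTF4	WDHD1
CTF8	CHTF8
DCC1	DSCC1
MRE11	MRE11A
RAD27	FEN1
RDH54	RAD54B
SCC1	RAD21
SCC2	NIPBL
SCC3	STAG1
SCC3	STAG2
SCC3	STAG3
SGS1	BLM
SGS1	WRN
SMC1	SMC1A
SMC3	SMC3
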