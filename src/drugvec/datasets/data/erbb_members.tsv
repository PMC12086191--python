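hsa04012	ErbB signaling pathway	Bosutinib	drug
hsa04012	ErbB signaling pathway	Canertinib dihydrochloride	drug
hsa04012	ErbB signaling pathway	Dabrafenib	drug
hsa04012	ErbB signaling pathway	Dacomitinib	drug
hsa04012	ErbB signaling pathway	Masoprocol	drug
hsa04012	ErbB signaling pathway	Neratinib	drug
hsa04012	ErbB signaling pathway	Nilotinib	drug
hsa04012	ErbB signaling pathway	Osimertinib	drug
hsa04012	ErbB signaling pathway	Pelitinib	drug
hsa04012	ErbB signaling pathway	Pimasertib	drug
hsa04012	ErbB signaling pathway	Poziotinib	drug
hsa04012	ErbB signaling pathway	Rociletinib	drug
hsa04012	ErbB signaling pathway	Saracatinib	drug
hsa04012	ErbB signaling pathway	Selumetinib	drug
hsa04012	ErbB signaling pathway	Temsirolimus	drug
hsa04012	ErbB signaling pathway	Tozasertib	drug
hsa04012	ErbB signaling pathway	Trametinib	drug
hsa04012	ErbB signaling pathway	Vandetanib	drug
hsa04012	ErbB signaling pathway	Varlitinib	drug
hsa04012	ErbB signaling pathway	ABL1	gene
hsa04012	ErbB signaling pathway	ABL2	gene
hsa04012	ErbB signaling pathway	AKT1	gene
hsa04012	ErbB signaling pathway	AKT2	gene
hsa04012	ErbB signaling pathway	AKT3	gene
hsa04012	ErbB signaling pathway	ARAF	gene
hsa04012	ErbB signaling pathway	AREG	gene
hsa04012	ErbB signaling pathway	BAD	gene
hsa04012	ErbB signaling pathway	BRAF	gene
hsa04012	ErbB signaling pathway	BTC	gene
hsa04012	ErbB signaling pathway	CAMK2A	gene
hsa04012	ErbB signaling pathway	CAMK2B	gene
hsa04012	ErbB signaling pathway	CAMK2D	gene
hsa04012	ErbB signaling pathway	CAMK2G	gene
hsa04012	ErbB signaling pathway	CBL	gene
hsa04012	ErbB signaling pathway	CBLB	gene
hsa04012	ErbB signaling pathway	CDKN1A	gene
hsa04012	ErbB signaling pathway	CDKN1B	gene
hsa04012	ErbB signaling pathway	CRK	gene
hsa04012	ErbB signaling pathway	CRKL	gene
hsa04012	ErbB signaling pathway	EGF	gene
hsa04012	ErbB signaling pathway	EGFR	gene
hsa04012	ErbB signaling pathway	EIF4EBP1	gene
hsa04012	ErbB signaling pathway	ELK1	gene
hsa04012	ErbB signaling pathway	ERBB2	gene
hsa04012	ErbB signaling pathway	ERBB3	gene
hsa04012	ErbB signaling pathway	ERBB4	gene
hsa04012	ErbB signaling pathway	EREG	gene
hsa04012	ErbB signaling pathway	GAB1	gene
hsa04012	ErbB signaling pathway	GRB2	gene
hsa04012	ErbB signaling pathway	GSK3B	gene
hsa04012	ErbB signaling pathway	HBEGF	gene
hsa04012	ErbB signaling pathway	HRAS	gene
hsa04012	ErbB signaling pathway	JUN	gene
hsa04012	ErbB signaling pathway	KRAS	gene
hsa04012	ErbB signaling pathway	MAP2K1	gene
hsa04012	ErbB signaling pathway	MAP2K2	gene
hsa04012	ErbB signaling pathway	MAP2K4	gene
hsa04012	ErbB signaling pathway	MAP2K7	gene
hsa04012	ErbB signaling pathway	MAPK1	gene
hsa04012	ErbB signaling pathway	MAPK10	gene
hsa04012	ErbB signaling pathway	MAPK3	gene
hsa04012	ErbB signaling pathway	MAPK8	gene
hsa04012	ErbB signaling pathway	MAPK9	gene
hsa04012	ErbB signaling pathway	MTOR	gene
hsa04012	ErbB signaling pathway	MYC	gene
hsa04012	ErbB signaling pathway	NCK1	gene
hsa04012	ErbB signaling pathway	NCK2	gene
hsa04012	ErbB signaling pathway	NRAS	gene
hsa04012	ErbB signaling pathway	NRG1	gene
hsa04012	ErbB signaling pathway	NRG2	gene
hsa04012	ErbB signaling pathway	NRG3	gene
hsa04012	ErbB signaling pathway	NRG4	gene
hsa04012	ErbB signaling pathway	PAK1	gene
hsa04012	ErbB signaling pathway	PAK2	gene
hsa04012	ErbB signaling pathway	PAK3	gene
hsa04012	ErbB signaling pathway	PAK4	gene
hsa04012	ErbB signaling pathway	PAK5	gene
hsa04012	ErbB signaling pathway	PAK6	gene
hsa04012	ErbB signaling pathway	PIK3CA	gene
hsa04012	ErbB signaling pathway	PIK3CB	gene
hsa04012	ErbB signaling pathway	PIK3CD	gene
hsa04012	ErbB signaling pathway	PIK3R1	gene
hsa04012	ErbB signaling pathway	PIK3R2	gene
hsa04012	ErbB signaling pathway	PIK3R3	gene
hsa04012	ErbB signaling pathway	PLCG1	gene
hsa04012	ErbB signaling pathway	PLCG2	gene
hsa04012	ErbB signaling pathway	PRKCA	gene
hsa04012	ErbB signaling pathway	PRKCB	gene
hsa04012	ErbB signaling pathway	PRKCG	gene
hsa04012	ErbB signaling pathway	PTK2	gene
hsa04012	ErbB signaling pathway	RAF1	gene
hsa04012	ErbB signaling pathway	RPS6KB1	gene
hsa04012	ErbB signaling pathway	RPS6KB2	gene
hsa04012	ErbB signaling pathway	SHC1	gene
hsa04012	ErbB signaling pathway	SHC2	gene
hsa04012	ErbB signaling pathway	SHC3	gene
hsa04012	ErbB signaling pathway	SHC4	gene
hsa04012	ErbB signaling pathway	SOS1	gene
hsa04012	ErbB signaling pathway	SOS2	gene
hsa04012	ErbB signaling pathway	SRC	gene
hsa04012	ErbB signaling pathway	STAT5A	gene
hsa04012	ErbB signaling pathway	STAT5B	gene
hsa04012	ErbB signaling pathway	TGFA	gene
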