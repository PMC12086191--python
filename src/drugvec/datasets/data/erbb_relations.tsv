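Bosutinib	ABL1
Bosutinib	SRC
Canertinib dihydrochloride	EGFR
Canertinib dihydrochloride	ERBB2
Canertinib dihydrochloride	ERBB3
Canertinib dihydrochloride	ERBB4
Dabrafenib	BRAF
Dacomitinib	EGFR
Dacomitinib	ERBB2
Dacomitinib	ERBB4
Masoprocol	EGFR
Neratinib	EGFR
Neratinib	ERBB2
Neratinib	ERBB4
Nilotinib	ABL1
Osimertinib	EGFR
Pelitinib	EGFR
Pimasertib	MAP2K1
Pimasertib	MAP2K2
Poziotinib	EGFR
Poziotinib	ERBB2
Rociletinib	EGFR
Saracatinib	ABL1
Saracatinib	SRC
Selumetinib	MAP2K1
Selumetinib	MAP2K2
Temsirolimus	MTOR
Tozasertib	ABL1
Trametinib	MAP2K1
Trametinib	MAP2K2
Vandetanib	EGFR
Varlitinib	EGFR
Varlitinib	ERBB2
Varlitinib	ERBB4
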