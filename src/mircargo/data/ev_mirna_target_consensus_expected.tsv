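mirna_id	gene_symbol
miR-365a-3p/miR-365b-3p	CMTM3
miR-29b-3p	CDCA4
miR-29b-3p	CD276
miR-29b-3p	SP1
miR-29b-3p	CDKN1A
miR-29b-3p	COL1A1
miR-29b-3p	ETV4
miR-29b-3p	NCOR2
miR-140-5p	CAPN1
miR-140-5p	HDAC7
miR-152-3p	BTBD2
miR-152-3p	CDC25B
miR-152-3p	UBASH3B
miR-152-3p	NPTN
miR-34a-5p	ALDOA
miR-34a-5p	SLC25A23
miR-30b-5p/miR-30c-5p	ARL4C
miR-30b-5p/miR-30c-5p	NT5E
miR-30b-5p/miR-30c-5p	MIER2
miR-30b-5p/miR-30c-5p	PPP1R18
miR-30b-5p/miR-30c-5p	ATL2
miR-30b-5p/miR-30c-5p	NCOR2
miR-26a-5p	ARL4C
miR-26a-5p	REEP4
miR-26a-5p	TMEM135
miR-26a-5p	HMGA1
let-7e-5p/let-7g-5p	PLXND1
let-7e-5p/let-7g-5p	EFHD2
let-7e-5p/let-7g-5p	GALE
let-7e-5p/let-7g-5p	IGF2BP3
let-7e-5p/let-7g-5p	ATG16L1
let-7e-5p/let-7g-5p	HMGA1
let-7e-5p/let-7g-5p	MDFI
let-7e-5p/let-7g-5p	RRM2
let-7e-5p/let-7g-5p	CDC34
miR-195-5p	TMEM135
miR-195-5p	CMC1
miR-185-5p	FN1
miR-185-5p	RHOA
miR-185-5p	CNIH2
miR-324-5p	SMARCA4
miR-324-5p	SP1
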