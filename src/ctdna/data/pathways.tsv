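pathway	gene	role
cell cycle	CDKN2A	tsg
cell cycle	CDKN2B	tsg
cell cycle	CDKN1A	tsg
cell cycle	CDKN1B	tsg
cell cycle	CCND1	oncogene
cell cycle	CCND2	oncogene
cell cycle	CCND3	oncogene
cell cycle	CCNE1	oncogene
cell cycle	CDK4	oncogene
cell cycle	CDK6	oncogene
cell cycle	RB1	tsg
cell cycle	E2F1	oncogene
cell cycle	E2F3	oncogene
Hippo	NF2	tsg
Hippo	LATS1	tsg
Hippo	LATS2	tsg
Hippo	STK3	tsg
Hippo	STK4	tsg
Hippo	SAV1	tsg
Hippo	YAP1	oncogene
Hippo	TAOK1	tsg
Hippo	TAOK2	tsg
Hippo	WWC1	tsg
Hippo	FAT1	tsg
Myc	MYC	oncogene
Myc	MYCN	oncogene
Myc	MYCL	oncogene
Myc	MAX	tsg
Myc	MGA	tsg
Myc	MXD1	tsg
Myc	MNT	tsg
Notch	NOTCH1	tsg
Notch	NOTCH2	tsg
Notch	NOTCH3	tsg
Notch	NOTCH4	tsg
Notch	FBXW7	tsg
Notch	CREBBP	tsg
Notch	EP300	tsg
Notch	SPEN	tsg
Notch	NCOR1	tsg
Notch	NCOR2	tsg
Nrf2	NFE2L2	oncogene
Nrf2	KEAP1	tsg
Nrf2	CUL3	tsg
PI3K	PIK3CA	oncogene
PI3K	PIK3CB	oncogene
PI3K	PIK3R1	tsg
PI3K	PIK3R2	tsg
PI3K	PTEN	tsg
PI3K	AKT1	oncogene
PI3K	AKT2	oncogene
PI3K	AKT3	oncogene
PI3K	MTOR	oncogene
PI3K	TSC1	tsg
PI3K	TSC2	tsg
PI3K	RICTOR	oncogene
PI3K	RPTOR	oncogene
PI3K	STK11	tsg
PI3K	INPP4B	tsg
PI3K	PPP2R1A	tsg
PI3K	RHEB	oncogene
RTK-RAS	EGFR	oncogene
RTK-RAS	ERBB2	oncogene
RTK-RAS	ERBB3	oncogene
RTK-RAS	ERBB4	oncogene
RTK-RAS	MET	oncogene
RTK-RAS	ALK	oncogene
RTK-RAS	ROS1	oncogene
RTK-RAS	RET	oncogene
RTK-RAS	FGFR1	oncogene
RTK-RAS	FGFR2	oncogene
RTK-RAS	FGFR3	oncogene
RTK-RAS	FGFR4	oncogene
RTK-RAS	KIT	oncogene
RTK-RAS	PDGFRA	oncogene
RTK-RAS	KRAS	oncogene
RTK-RAS	NRAS	oncogene
RTK-RAS	HRAS	oncogene
RTK-RAS	BRAF	oncogene
RTK-RAS	RAF1	oncogene
RTK-RAS	ARAF	oncogene
RTK-RAS	MAP2K1	oncogene
RTK-RAS	MAP2K2	oncogene
RTK-RAS	NF1	tsg
RTK-RAS	PTPN11	oncogene
RTK-RAS	SOS1	oncogene
RTK-RAS	RIT1	oncogene
RTK-RAS	RASA1	tsg
RTK-RAS	CBL	tsg
TGFbeta	TGFBR1	tsg
TGFbeta	TGFBR2	tsg
TGFbeta	SMAD2	tsg
TGFbeta	SMAD3	tsg
TGFbeta	SMAD4	tsg
TGFbeta	ACVR2A	tsg
TGFbeta	ACVR1B	tsg
p53	TP53	tsg
p53	MDM2	oncogene
p53	MDM4	oncogene
p53	ATM	tsg
p53	CHEK2	tsg
p53	RPS6KA3	tsg
Wnt	APC	tsg
Wnt	CTNNB1	oncogene
Wnt	AXIN1	tsg
Wnt	AXIN2	tsg
Wnt	TCF7L2	tsg
Wnt	RNF43	tsg
Wnt	ZNRF3	tsg
Wnt	AMER1	tsg
Wnt	GSK3B	tsg
Wnt	DKK1	tsg
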