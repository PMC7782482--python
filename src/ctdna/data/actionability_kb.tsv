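gene	pattern	pattern_kind	cancer_type	level	drugs
EGFR	e19del	positional_class	NSCLC	1	gefitinib;erlotinib;afatinib;osimertinib
EGFR	L858R	protein_change	NSCLC	1	gefitinib;erlotinib;afatinib;osimertinib
EGFR	T790M	protein_change	NSCLC	1	osimertinib
EGFR	G719A	protein_change	NSCLC	2	afatinib
ALK	fusion	alteration_class	NSCLC	1	crizotinib;alectinib
ROS1	fusion	alteration_class	NSCLC	1	crizotinib;entrectinib
BRAF	V600E	protein_change	melanoma	1	dabrafenib;vemurafenib
BRAF	V600E	protein_change	NSCLC	1	dabrafenib+trametinib
BRAF	V600E	protein_change	colorectal	2	encorafenib+cetuximab
ERBB2	amplification	alteration_class	breast	1	trastuzumab;pertuzumab
ERBB2	amplification	alteration_class	UGI	1	trastuzumab
PIK3CA	H1047R	protein_change	breast	1	alpelisib
PIK3CA	E545K	protein_change	breast	1	alpelisib
KIT	e11mut	positional_class	GIST	1	imatinib
PDGFRA	D842V	protein_change	GIST	1	avapritinib
KRAS	G12C	protein_change	NSCLC	1	sotorasib;adagrasib
MET	e14skip	positional_class	NSCLC	1	capmatinib;tepotinib
RET	fusion	alteration_class	NSCLC	1	selpercatinib;pralsetinib
IDH1	R132H	protein_change	biliary	1	ivosidenib
FGFR2	fusion	alteration_class	biliary	1	pemigatinib
AKT1	E17K	protein_change	breast	3	capivasertib
ATM	truncating	alteration_class	prostate	3	olaparib
NF1	truncating	alteration_class	neurofibroma	4	selumetinib
TSC1	truncating	alteration_class	bladder	3	everolimus
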