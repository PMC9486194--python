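CMS4_TEST	4-gene CMS4 diagnostic panel	PDGFRA	PDGFRB	PDGFC	KIT
CMS4_UP	synthetic stand-in: mesenchymal genes up in CMS4	ZEB1	VIM	CD36	FN1	TWIST1	SNAI2	TGFB1	COL1A1	COL3A1	SPARC	THBS2	INHBA
ADHERENS_JUNCTION	synthetic stand-in: adherens junction components	CDH1	CTNNA1	CTNNB1	CTNND1	JUP	AFDN	NECTIN2	ACTN1
DESMOSOME	synthetic stand-in: desmosome components	JUP	DSP	DSG2	DSC2	PKP2	PKP3	PERP
CELL_CLUSTER	synthetic stand-in: circulating tumor cell cluster genes	KRT8	KRT18	KRT19	EPCAM	CLDN4	CLDN7	PLAKOPHILIN
WNT_TARGETS	synthetic stand-in: WNT target genes	AXIN2	LGR5	ASCL2	RNF43	SP5	NKD1	TCF7	LEF1
MYC_TARGETS	synthetic stand-in: MYC target genes	NPM1	NCL	RPL3	RPS6	EIF4E	CDK4	ODC1	SRM
CELL_CYCLE	synthetic stand-in: cell-cycle pathway genes	MKI67	CCNB1	CCNE1	CDK1	CDC20	BUB1	PLK1	AURKA	E2F1	MCM2
MTORC1_TOP	synthetic stand-in: TOP mRNA mTORC1 targets	RPS6	RPL11	RPL32	RPS3	RPS8	EEF1A1	EEF2	EIF3E	RPTOR	MLST8	DEPTOR
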