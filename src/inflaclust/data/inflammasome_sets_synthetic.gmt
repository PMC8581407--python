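IC_CORE	synthetic inflammasome-signaling gene set	NLRP1	NLRP3	NLRC4	NLRP6	NLRP7	NLRP2	NLRP9	NLRP12	AIM2	IFI16	PYCARD	NAIP	MEFV	CASP1	CASP4
CASP1_UP	synthetic inflammasome-signaling gene set	IL1B	IL18	CXCL8	TNF	IL6	CCL2	CCL20	CXCL1	CXCL2	CXCL3	PTGS2	NOS2	NFKB1	NFKBIA	TNFAIP3	SOD2	ICAM1	VCAM1	IRF1	SOCS3	STAT3	JUNB	FOSB	PLAUR
CASP1_DN	synthetic inflammasome-signaling gene set	MKI67	CCNB1	CDK1	TOP2A	BIRC5	AURKA	PLK1	CCNA2	BUB1	TYMS
GSDMD_UP	synthetic inflammasome-signaling gene set	HMGB1	GSDME	CASP3	CASP7	IL1A	IL36G	CALR	HSPA5	DDIT3
GSDMD_DN	synthetic inflammasome-signaling gene set	BCL2	MCL1	BIRC3	XIAP
IL1B_UP	synthetic inflammasome-signaling gene set	CXCL8	CXCL5	CXCL6	CXCL10	CXCL11	CCL3	CCL4	CCL5	CCL7	CCL8	CCL11	MMP1	MMP3	MMP9	MMP13	SAA1	SAA2	CRP	LCN2	S100A8	S100A9	S100A12	SELE	SELP	CSF2	CSF3	IL11	IL23A	IL32	IL36A	LIF	OSM	PTX3	SERPINE1	PLAU	F3	TLR2	CD14	FPR1	FPR2	C3	C5AR1	CFB	BDKRB1	KNG1	PTGER2	PTGES	ALOX5AP	NCF2	CYBB
IL1B_DN	synthetic inflammasome-signaling gene set	ALB	APOA1	APOA2	APOB	APOC3	TTR	TF	CYP1A2	CYP2E1	CYP3A4	SLC10A1	ASGR1	ASGR2	ADH1B	ADH1C	ALDOB	G6PC1	PCK1	FBP1	OTC	CPS1	ARG1
IL18_UP	synthetic inflammasome-signaling gene set	IFNG	GZMB	PRF1	KLRD1	NCR1	IL12RB2
IL18_DN	synthetic inflammasome-signaling gene set	IL4	IL5
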