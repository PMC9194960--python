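Antigen_Processing_and_Presentation	Antigen_Processing_and_Presentation	HLA-A	HLA-B	HLA-C	HLA-DRA	HLA-DRB1	HLA-DQA1	HLA-DPB1	TAP1	TAP2	TAPBP	B2M	PSMB8	PSMB9	CALR	CANX	ERAP1	CTSS	CD74
Antimicrobials	Antimicrobials	DEFB1	DEFB4A	DEFA1	CAMP	LTF	LYZ	S100A8	S100A9	S100A12	LCN2	ELANE	MPO	BPI	RNASE3	SLPI	PRTN3
BCR_Signaling_Pathway	BCR_Signaling_Pathway	CD79A	CD79B	CD19	CD81	CR2	BLNK	BTK	SYK	LYN	FYN	PLCG2	PIK3CD	PRKCB	CARD11	BCL10	MALT1	VAV1
Chemokines	Chemokines	CCL2	CCL3	CCL4	CCL5	CCL7	CCL8	CCL11	CCL19	CCL20	CCL21	CXCL1	CXCL2	CXCL8	CXCL9	CXCL10	CXCL11	CXCL12	CXCL13	CX3CL1	XCL1
Chemokine_Receptors	Chemokine_Receptors	CCR1	CCR2	CCR3	CCR4	CCR5	CCR6	CCR7	CCR8	CCR9	CCR10	CXCR1	CXCR2	CXCR3	CXCR4	CXCR5	CXCR6	CX3CR1	XCR1	ACKR3
Cytokines	Cytokines	IL1A	IL1B	IL2	IL4	IL5	IL6	IL7	IL9	IL10	IL12A	IL12B	IL13	IL15	IL17A	IL18	IL21	IL22	IL23A	IL33	TNF	LTA	CSF1	CSF2	CSF3	OSM	LIF
Cytokine_Receptors	Cytokine_Receptors	IL1R1	IL1R2	IL2RA	IL2RB	IL2RG	IL4R	IL6R	IL6ST	IL7R	IL10RA	IL10RB	IL12RB1	IL12RB2	IL13RA1	IL15RA	IL17RA	IL18R1	IL21R	CSF1R	CSF2RA	CSF2RB	CSF3R	OSMR	LIFR
Interferons	Interferons	IFNA1	IFNA2	IFNA4	IFNA5	IFNA6	IFNA7	IFNA8	IFNA10	IFNA13	IFNA14	IFNA16	IFNA17	IFNA21	IFNB1	IFNG	IFNE	IFNK	IFNW1	IFNL1	IFNL2	IFNL3
Interferon_Receptors	Interferon_Receptors	IFNAR1	IFNAR2	IFNGR1	IFNGR2	IFNLR1	IL10RB	JAK1	JAK2	TYK2	STAT1	STAT2	IRF1	IRF3	IRF7	IRF9	ISG15	MX1	OAS1
Interleukins	Interleukins	IL1A	IL1B	IL1RN	IL2	IL3	IL4	IL5	IL6	IL7	IL9	IL10	IL11	IL12A	IL12B	IL13	IL15	IL16	IL17A	IL17F	IL18	IL19	IL20	IL21	IL22	IL23A	IL24	IL25	IL26	IL27	IL32	IL33	IL34	IL36A	IL36B	IL36G	IL37
Interleukin_Receptors	Interleukin_Receptors	IL1R1	IL1R2	IL1RL1	IL1RL2	IL2RA	IL2RB	IL2RG	IL3RA	IL4R	IL5RA	IL6R	IL7R	IL9R	IL10RA	IL10RB	IL11RA	IL12RB1	IL12RB2	IL13RA1	IL13RA2	IL15RA	IL17RA	IL17RB	IL17RC	IL17RE	IL18R1	IL18RAP	IL20RA	IL20RB	IL21R	IL22RA1	IL22RA2	IL23R	IL27RA
Natural_Killer_Cell_Cytotoxicity	Natural_Killer_Cell_Cytotoxicity	KLRD1	KLRK1	KLRC1	KLRC2	NCR1	NCR2	NCR3	KIR2DL1	KIR2DL3	KIR3DL1	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1	GNLY	FASLG	SH2D1A	SH2D1B	CD226	CD244
TCR_Signaling_Pathway	TCR_Signaling_Pathway	CD3D	CD3E	CD3G	CD247	CD4	CD8A	CD8B	LCK	FYN	ZAP70	LAT	SLP76	ITK	PLCG1	PRKCQ	CARD11	GRAP2	CD28	CTLA4	ICOS	PDCD1
TGFb_Family_Members	TGFb_Family_Members	TGFB1	TGFB2	TGFB3	BMP1	BMP2	BMP4	BMP6	BMP7	BMP8A	GDF5	GDF9	GDF11	GDF15	INHBA	INHBB	INHBE	MSTN	NODAL	LEFTY1	LEFTY2	AMH
TGFb_Family_Member_Receptors	TGFb_Family_Member_Receptors	TGFBR1	TGFBR2	TGFBR3	BMPR1A	BMPR1B	BMPR2	ACVR1	ACVR1B	ACVR1C	ACVR2A	ACVR2B	ACVRL1	AMHR2	ENG	BAMBI
TNF_Family_Members	TNF_Family_Members	TNF	LTA	LTB	FASLG	TNFSF4	TNFSF8	TNFSF9	TNFSF10	TNFSF11	TNFSF12	TNFSF13	TNFSF13B	TNFSF14	TNFSF15	TNFSF18	CD40LG	CD70	EDA
TNF_Family_Member_Receptors	TNF_Family_Member_Receptors	TNFRSF1A	TNFRSF1B	LTBR	FAS	TNFRSF4	TNFRSF8	TNFRSF9	TNFRSF10A	TNFRSF10B	TNFRSF11A	TNFRSF11B	TNFRSF12A	TNFRSF13B	TNFRSF13C	TNFRSF14	TNFRSF17	TNFRSF18	TNFRSF21	TNFRSF25	CD27	CD40	NGFR
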