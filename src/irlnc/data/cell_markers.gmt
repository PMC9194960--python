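T_cells	T_cells	CD3D	CD3E	CD3G	CD247	CD5	TRAC	TRBC1	LCK
CD8_T_cells	CD8_T_cells	CD8A	CD8B	GZMK	EOMES
Cytotoxic_lymphocytes	Cytotoxic_lymphocytes	GZMA	GZMB	GZMH	PRF1	GNLY	KLRD1	NKG7	CTSW
B_lineage	B_lineage	CD19	MS4A1	CD79A	CD79B	IGKC	BANK1	PAX5	CD22
NK_cells	NK_cells	NCR1	KIR2DL3	KIR3DL1	NCAM1	KLRC1	XCL2
Monocytic_lineage	Monocytic_lineage	CD14	CD163	CSF1R	ITGAM	FCGR1A	MSR1	CD68	LILRB4
Myeloid_dendritic_cells	Myeloid_dendritic_cells	CD1A	CD1B	CD1E	FLT3	CLEC10A	WDFY4
Neutrophils	Neutrophils	FCGR3B	CSF3R	CXCR2	FPR1	S100A8	S100A9	CEACAM3
Endothelial_cells	Endothelial_cells	PECAM1	CDH5	VWF	KDR	CLDN5	ESAM	TEK	CD34
Fibroblasts	Fibroblasts	COL1A1	COL1A2	COL3A1	DCN	PDGFRB	FAP	LUM	THY1
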