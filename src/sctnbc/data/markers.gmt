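epithelial	mammary epithelial markers	EPCAM	KRT8	KRT18	KRT19	KRT5	KRT14	CDH1	ELF3	CLDN4	CLDN7	KRT7	MUC1	SLPI	GATA3	FOXA1
t_cell	T lymphocyte markers	CD3D	CD3E	CD3G	CD2	CD7	TRAC	TRBC2	IL7R	CCL5	LCK	CD8A	CD4
b_cell	B lymphocyte markers	CD79A	CD79B	MS4A1	CD19	IGHM	IGKC	BANK1	BLNK	VPREB3
macrophage	macrophage markers	CD14	CD68	CD163	LYZ	AIF1	FCGR3A	CSF1R	ITGAM	MSR1	MRC1
stroma	fibroblast and stromal markers	COL1A1	COL1A2	COL3A1	DCN	LUM	FAP	PDGFRA	PDGFRB	THY1	ACTA2	TAGLN	FN1
endothelial	endothelial markers	PECAM1	VWF	CDH5	CLDN5	FLT1	KDR	TEK	ENG	PLVAP
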