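T_cells	default marker set, user-replaceable	CD3D	CD3E	CD2	TRAC
CD8_T_cells	default marker set, user-replaceable	CD8A	CD8B	GZMK
CD4_T_cells	default marker set, user-replaceable	CD4	IL7R	CD40LG
B_cells	default marker set, user-replaceable	CD19	MS4A1	CD79A
NK_cells	default marker set, user-replaceable	NKG7	KLRD1	NCR1	KLRK1
Treg	default marker set, user-replaceable	FOXP3	IL2RA	IKZF2
pDCs	default marker set, user-replaceable	LILRA4	CLEC4C	IL3RA
Dendritic_cells	default marker set, user-replaceable	CD1C	BATF3	FLT3
TAM	default marker set, user-replaceable	CD68	CD163	MRC1	MSR1
MDSC	default marker set, user-replaceable	ITGAM	S100A8	S100A9	ARG1
Monocytes	default marker set, user-replaceable	CD14	FCN1	LYZ
Neutrophils	default marker set, user-replaceable	FCGR3B	CSF3R	CXCR2
Mast_cells	default marker set, user-replaceable	TPSAB1	CPA3	MS4A2
TLS	default marker set, user-replaceable	CXCL13	CCL19	CCL21	LTB
CYT	default marker set, user-replaceable	GZMA	PRF1
IFN_gamma	default marker set, user-replaceable	IFNG	STAT1	IDO1	CXCL9	CXCL10
IFN_type_I	default marker set, user-replaceable	ISG15	IFI6	MX1	OAS1
Checkpoint	default marker set, user-replaceable	PDCD1	CTLA4	CD274	LAG3	HAVCR2	TIGIT
Antigen_presentation	default marker set, user-replaceable	HLA-A	HLA-B	TAP1	B2M
TGF_beta	default marker set, user-replaceable	TGFB1	TGFBR2	SMAD3
Pan_F_TBRs	default marker set, user-replaceable	ACTA2	COL4A1	TAGLN	SH3PXD2A
ECM	default marker set, user-replaceable	COL1A1	COL3A1	FN1	LUM
Stroma	default marker set, user-replaceable	FAP	PDGFRB	THY1	DCN
CAF	default marker set, user-replaceable	PDPN	PDGFRA	POSTN
Wnt_beta_catenin	default marker set, user-replaceable	CTNNB1	WNT5A	AXIN2	TCF7
Angiogenesis	default marker set, user-replaceable	VEGFA	PECAM1	KDR	CDH5
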