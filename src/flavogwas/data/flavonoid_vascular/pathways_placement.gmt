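VEGFA-VEGFR2 Signaling Pathway	WikiPathways	CSK	MKNK1	MYO6	PTPRJ	SMARCA2	TNXB
Regulation of actin cytoskeleton	both	BRK1	CSK	GNA13	SOS2
Adherens junction	KEGG	PTPRJ	TCF7L2	YES1
Angiopoietin Like Protein 8 Regulatory Pathway	WikiPathways	LPL	PRKAG2	SOS2
ECM-receptor interaction	KEGG	NPNT	TNXB	VTN
Focal adhesion	KEGG	SOS2	TNXB	VTN
Apelin signaling pathway	KEGG	GNA13	PRKAG2
Cholesterol metabolism	KEGG	LDLR	LPL
Composition of Lipid Particles	WikiPathways	LDLR	LPL
Fluid shear stress and atherosclerosis	KEGG	BMPR1B	GSTA4
Glycerolipid metabolism	KEGG	ALDH2	LPL
Metabolic pathway of LDL, HDL and TG, including diseases	WikiPathways	LDLR	LPL
Platelet activation	KEGG	GNA13	LYN
Statin Pathway	WikiPathways	LDLR	LPL
Chemokine signaling pathway	both	CSK	LYN	SOS2
Cytokine-cytokine receptor interaction	KEGG	BMPR1B	GDF10	LTB
NF-kappa B signaling pathway	both	LTB	LYN	TAB2
Regulation of toll-like receptor signaling pathway	WikiPathways	IRF5	SARM1	TAB2
B cell receptor signaling pathway	KEGG	LYN	SOS2
Interleukin-11 Signaling Pathway	WikiPathways	FES	YES1
Natural killer cell mediated cytotoxicity	KEGG	NCR3	SOS2
Structural Pathway of Interleukin 1 (IL-1)	WikiPathways	MKNK1	TAB2
TNF signaling pathway	KEGG	DAB2IP	TAB2
Toll-like receptor signaling pathway	both	IRF5	TAB2
MAPK signaling pathway	both	MKNK1	SOS2	STK3	TAB2
PI3K-Akt signaling pathway	both	MCL1	SOS2	TNXB	VTN
EGF/EGFR Signaling Pathway	WikiPathways	CSK	SOS2	TWIST1
Insulin signaling pathway	KEGG	MKNK1	PRKAG2	SOS2
Sterol Regulatory Element-Binding Proteins (SREBP) signalling	WikiPathways	LDLR	LPL	PRKAG2
cGMP-PKG signaling pathway	KEGG	ATP2B1	GNA13
FoxO signaling pathway	KEGG	PRKAG2	SOS2
Jak-STAT signaling pathway	KEGG	MCL1	SOS2
Phospholipase D signaling pathway	KEGG	GNA13	SOS2
Wnt Signaling Pathway and Pluripotency	WikiPathways	LDLR	TCF7L2
NRF2 pathway	WikiPathways	GSTA4	SLC39A8
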