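APOE
ARNTL
CERS5
CXCL8
CYP11B2
EBF1
EDNRA
FOXC1
FOXO1
GSE1
IL6
IRF5
MKNK1
MMP3
MYO9B
NFATC2
NPAS3
PLCE1
PPARG
PTPN11
SMARCA4
TCF20
TCF7L2
TNF
ZBTB10
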