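APOE
EBF1
FOXC1
IL6
IRF5
KPNA2
LDLR
LSP1
MYO6
NCOR2
NCR3
NFATC2
NR1H3
PNPT1
PPARG
PRDM16
PTPN11
RPTOR
SMARCA4
TNF
USP8
ZBTB10
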