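CAPZA1
FSTL4
GNA13
LSP1
MRPL23
MS4A4A
NCR3
NOL10
NUMB
SARM1
SH2B3
SYTL3
TCF20
ZMYM2
ZNF831
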