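ERAP1
FMN2
FOXO1
HIC1
RPTOR
TCF7L2
ZNF746
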