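H19
KPNA2
LDLR
PBRM1
TNF
ZNF746
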