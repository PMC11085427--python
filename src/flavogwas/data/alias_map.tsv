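# alias	canonical
PPRG	PPARG
IL8	CXCL8
MCP-1	CCL2
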