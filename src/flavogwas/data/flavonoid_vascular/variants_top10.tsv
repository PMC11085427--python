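gene	rsid	consequence	frequency	clinical_significance
ALDH2	rs7296651	intron variant	0.497804
ALDH2	rs6489793	3 prime UTR variant	0.497604
ALDH2	rs2106697	not specified	0.496406
ALDH2	rs10774638	intron variant	0.492612
ALDH2	rs886205	2 KB upstream variant	0.491214
ALDH2	rs4767939	intron variant	0.419728
ALDH2	rs10774637	intron variant	0.419129
ALDH2	rs9971942	not specified	0.410743
ALDH2	rs10774639	not specified	0.410743
ALDH2	rs11066028	intron variant	0.372804
APOE	rs405509	2 KB upstream variant	0.471845
APOE	rs440446	missense variant, intron variant, synonymous variant	0.373802
APOE	rs769450	intron variant	0.327276
APOE	rs429358	missense variant	0.150559
APOE	rs7412	missense variant	0.0750799
APOE	rs769449	intron variant	0.0648962
APOE	rs1081105	500 B downstream variant	0.0301518
APOE	rs877973	5 prime UTR variant, intron variant	0.0159744
CAPZA1	rs3013440	intron variant	0.478435
CAPZA1	rs7524494	intron variant	0.478435
CAPZA1	rs7415820	intron variant	0.478035
CAPZA1	rs3103450	intron variant	0.478035
CAPZA1	rs2932536	intron variant	0.478035
CAPZA1	rs3013439	intron variant	0.477835
CAPZA1	rs12046329	intron variant	0.477835
CAPZA1	rs12046466	intron variant	0.477835
CAPZA1	rs12046208	intron variant	0.436502
CAPZA1	rs9429486	intron variant	0.435703
TNF	rs1800610	intron variant	0.100439
TNF	rs3093662	intron variant	0.0798722
TNF	rs3093664	intron variant	0.0788738
TNF	rs361525	2 KB upstream variant	0.0609026
TNF	rs3093661	intron variant	0.0521166
TNF	rs673	2 KB upstream variant	0.0191693
TNF	rs3093665	3 prime UTR variant	0.01877
TNF	rs2228088	synonymous variant	0.0175719
TNF	rs41297589	2 KB upstream variant	0.0105831
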