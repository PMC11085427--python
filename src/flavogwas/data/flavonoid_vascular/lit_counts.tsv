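gene	pool	category	count
MTHFR	deg	cvd_snp	394
LPL	deg	cvd_snp	92
LDLR	deg	cvd_snp	74
ALDH2	deg	cvd_snp	47
TCF7L2	deg	cvd_snp	34
MTHFR	deg	nutrition_snp	22
LPL	deg	nutrition_snp	14
LDLR	deg	nutrition_snp	5
TCF7L2	deg	nutrition_snp	5
APOE	ur	cvd_snp	383
IL6	ur	cvd_snp	233
TNF	ur	cvd_snp	140
LDLR	ur	cvd_snp	74
MMP3	ur	cvd_snp	46
CYP11B2	ur	cvd_snp	45
TCF7L2	ur	cvd_snp	34
PPRG	ur	cvd_snp	24
APOE	ur	nutrition_snp	26
IL6	ur	nutrition_snp	13
TNF	ur	nutrition_snp	10
PPARG	ur	nutrition_snp	6
LDLR	ur	nutrition_snp	5
TCF7L2	ur	nutrition_snp	5
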