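rsid	risk_allele	mapped_genes	trait	accessions	global_frequency	gene	role
rs671	A	ALDH2	Hypertension	GCST011141	0.0357	ALDH2	DEG in Paper 1
rs445925	G	APOE - APOC1	Atherosclerosis	GCST001231	0.8502	APOE	UR in Papers 1, 4, and 5
rs445925	A	APOE - APOC1	Atherosclerosis	GCST001231	0.1498	APOE	UR in Papers 1, 4, and 5
rs10745332	A	CAPZA1	Hypertension	GCST002627	0.8131	CAPZA1	DEG in Papers 2, 3, and 4
rs17030613	A	CAPZA1	Hypertension	GCST007707	0.7678	CAPZA1	DEG in Papers 2, 3, and 4
rs62524579	A	CYP11B2 - LY6E-DT	Hypertension	GCST007707	0.4794	CYP11B2	UR in Paper 4
rs12679242	T	CYP11B2	Hypertension	GCST007707	0.3470	CYP11B2	UR in Paper 4
rs6418	A	CYP11B2 - GML	Hypertension	GCST007707	0.6450	CYP11B2	UR in Paper 4
rs1799998	G	CYP11B2 - LY6E-DT	Hypertension	GCST011141	0.3472	CYP11B2	UR in Paper 4
rs12941507	C	GNA13 - AMZ2P1	Hypertension	GCST011952;GCST011953	0.0647	GNA13	DEG in Papers 2 and 3
rs4722172	G	IL6 - MTCYBP42	Atherosclerosis	GCST008474;GCST90061371	0.0595	IL6	UR in Papers 4 and 5
rs4728142	A	IRF5 - KCP	Hypertension	GCST006023	0.2945	IRF5	DEG in Paper 5; UR in Papers 4 and 5
rs6511720	T	LDLR	Atherosclerosis	GCST001231	0.0917	LDLR	DEG in Paper 1; UR in Papers 2 and 5
rs138294113	C	LDLR - SMARCA4	Atherosclerosis	GCST008474;GCST90061371	0.9095	LDLR	DEG in Paper 1; UR in Papers 2 and 5
rs322	A	LPL	Atherosclerosis	GCST008474;GCST90061371	0.7079	LPL	DEG in Paper 2
rs1973765	T	LSP1	Hypertension	GCST007707	0.5641	LSP1	DEG in Papers 3 and 4; UR in Paper 5
rs569550	T	LSP1	Hypertension	GCST007707	0.5765	LSP1	DEG in Papers 3 and 4; UR in Paper 5
rs661348	T	LSP1	Hypertension	GCST007707	0.6182	LSP1	DEG in Papers 3 and 4; UR in Paper 5
rs4980389	A	LSP1	Hypertension	GCST007707	0.4267	LSP1	DEG in Papers 3 and 4; UR in Paper 5
rs139537100	C	MKNK1 - MOB3C	Hypertension	GCST010477	0.999938	MKNK1	DEG in Paper 4; UR in Paper 4
rs566125	T	MMP3	Atherosclerosis	GCST008474;GCST90061371	0.0755	MMP3	UR in Paper 4
rs17367504		MTHFR	Hypertension	GCST009685		MTHFR	DEG in Paper 5
rs3798440 x rs9350602	A x C	no mapped genes x MYO6	Hypertension	GCST001085	0.8972	MYO6	DEG in Paper 4; UR in Paper 5
rs2515920	T	NCR3 - UQCRHP1	Hypertension	GCST010477	0.0495	NCR3	DEG in Papers 2 and 5; UR in Paper 5
rs17036160	C	PPARG	Arterial stiffness	GCST008403	0.9319	PPARG	UR in Papers 4 and 5
rs704	A	SARM1 - VTN	Hypertension	GCST90000064	0.5551	SARM1	DEG in Papers 4 and 5
rs17478227		TCF20	Arterial stiffness	GCST007846		TCF20	DEG in Papers 1 and 4; UR in Paper 4
rs7903146	T	TCF7L2	Atherosclerosis	GCST008474;GCST90061371	0.2278	TCF7L2	DEG in Paper 1; UR in Papers 3 and 4
rs769177	G	TNF - LTB	Hypertension	GCST010477		TNF	UR in Papers 2, 4 and 5
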