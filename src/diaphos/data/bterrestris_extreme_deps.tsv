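accession	description	ratio	p	gene	mw_kda	group
A0A6P3D6E6	leucine-rich repeat and immunoglobulin-like domain-containing nogo receptor-interacting protein 2	11.493	5.98e-5	LOC100648620	103.4	PD/D
A0A6P3DB00	CDK-activating kinase assembly factor MAT1	8.873	1.055e-5	LOC100642207	36.711	PD/D
A0A6P5HS32	Transmembrane protease serine	5.623	0.0093336	LOC110119488	65.551	PD/D
A0A6P3UB32	putative inorganic phosphate cotransporter	5.601	9.643e-5	LOC100647822	53.886	PD/D
A0A6P3TTL0	suppressor APC domain-containing protein 2	5.545	0.0015442	LOC100647337	51.622	PD/D
A0A6P5I390	E3 ubiquitin-protein ligase Rnf220	5.301	0.0002411	LOC100643542	35.027	PD/D
A0A6P3DC42	disheveled-associated activator of morphogenesis 1	5.122	9.54e-6	LOC100650848	123.68	PD/D
A0A6P5IBX2	anoctamin-1	0.551	0.0077095	LOC100646632	115.18	FPD/PD
A0A6P3DGE6	pancreatic lipase-related protein 2	0.99	0.8897713	LOC100645800	34.752	FPD/PD
A0A6P3U8X6	phospholipase A2	1.159	0.2525801	LOC100651730	22.336	FPD/PD
A0A6P3TVD7	cation-independent mannose-6-phosphate receptor	0.898	0.098125	LOC100651480	82.845	FPD/PD
A0A6P3DNC4	serine protease inhibitor 3/4	1.356	0.0453889	LOC100652301	35.236	FPD/PD
A0A6P3DFC5	nuclear factor related to kappa-B-binding protein	1.138	0.1405269	LOC100649343	168.64	FPD/PD
A0A6P5HLS9	protein toll	1.775	0.0262693	LOC100651716	125.92	FPD/PD
A0A6P3U2L5	Apoptosis-stimulating of p53	1.607	0.02605	LOC100646232	139.27	FPD/PD
A0A6P3TPE5	venom protease	1.551	0.0013554	LOC100642484	32.966	FPD/PD
A0A6P3TWR2	TNF receptor-associated factor 5	2.023	0.0232261	LOC105665677	55.742	FPD/PD
A0A6P3UKF1	venom acid phosphatase Acph-1	1.208	0.1376568	LOC100647178	48.343	FPD/PD
A0A6P5I2Z1	major royal jelly protein 1	2.115	0.0755501	LOC100648898	41.083	FPD/PD
A0A6P3UGV4	basement membrane-specific heparan sulfate proteoglycan core protein	0.067	0.0001312	LOC100651429	468.9	FPD/PD
A0A6P5HLF4	CLIP domain-containing serine protease	1.181	0.0913721	LOC100652157	82.898	FPD/PD
A0A6P3TNQ5	alpha-glucosidase	1.321	0.0721932	LOC100643608	65.637	FPD/PD
A0A6P3DF18	facilitated trehalose transporter Tret1-lik	0.811	0.1431761	LOC100644978	76.971	FPD/PD
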