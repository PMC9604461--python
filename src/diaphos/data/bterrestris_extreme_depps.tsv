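accession	position	residue	description	ratio	p	gene	group
A0A6P3U5V0	91	S	RNA polymerase-associated protein LEO1	9.982	4.011e-5	LOC100652289	PD/D
A0A6P3DA37	471	S	dolichyl-diphosphooligosaccharide--protein glycosyltransferase subunit STT3B	9.306	0.0002187	LOC100647181	PD/D
A0A6P5IE28	166	S	catenin alpha	8.092	0.0001623	LOC100648462	PD/D
A0A6P5I410	505	T	splicing factor 3B subunit 2	8.01	0.0005079	LOC100643117	PD/D
A0A6P3TWI1	591	S	DDB1- and CUL4-associated factor 8	7.232	0.0001319	LOC100644051	PD/D
A0A6P3U5V0	119	S	RNA polymerase-associated protein LEO1	6.862	0.0001676	LOC100652289	PD/D
A0A6P3DB01	580	S	nucleolin	6.187	3.099e-6	LOC100644519	PD/D
A0A6P3UJ38	26	S	GD14428	6.181	3.796e-5	LOC100643604	PD/D
A0A6P3UFI4	228	T	microtubule-actin cross-linking factor 1	5.57	6.545e-5	LOC100647948	PD/D
A0A6P3UAY9	147	S	solute carrier family 25 member 38	5.54	4.793e-5	LOC100649391	PD/D
A0A6P3UJ22	273	S	60S ribosomal protein L5	5.503	0.006308	LOC100642874	PD/D
A0A6P5HLM2	926	S	trichohyalin	5.485	9.834e-5	LOC100646259	PD/D
A0A6P3U0R3	2381	S	golgin subfamily A member 4	5.469	0.0001002	LOC105665975	PD/D
A0A6P5I2T4	771	S	tau-tubulin kinase homolog Asator	5.344	0.0068525	LOC100646154	PD/D
A0A6P5HGT7	692	S	serine/threonine-protein kinase MARK2 isoform X11	5.248	0.000345	LOC100645231	PD/D
A0A6P5HR14	1421	T	myosin heavy chain, muscle	5.237	0.0001658	LOC100647343	PD/D
A0A6P3D774	1536	T	lysine-specific demethylase lid	5.103	0.0060939	LOC100648929	PD/D
A0A6P5HR09	5303	T	titin	5.094	0.0011792	LOC100643650	PD/D
A0A6P3D7R3	197	S	60S ribosomal protein L15	5.046	0.0008772	LOC100648934	PD/D
A0A6P3TLJ9	504	T	vitellogenin	10.046	0.0048077	LOC100650436	FPD/PD
A0A6P3U9T5	23	S	sugar transporter ERD6-like 8	8.168	0.0001362	LOC100644377	FPD/PD
A0A6P3U996	454	S	serine/arginine repetitive matrix protein 2	7.991	0.0094707	LOC100642774	FPD/PD
A0A6P3UGK1	319	S	jerky protein homolog-like	7.445	0.0183674	LOC105666848	FPD/PD
A0A6P3U6P7	1604	S	TBC1 domain family member 30	5.581	0.1101188	LOC100645056	FPD/PD
A0A6P3DHB6	22	T	synaptic vesicle membrane protein VAT-1 homolog-like	5.525	0.0003307	LOC100650297	FPD/PD
A0A6P3DFL1	81	S	Katnb1_0 protein	5.434	0.0002241	LOC100645647	FPD/PD
A0A6P3DF18	681	S	facilitated trehalose transporter Tret1-like	5.329	0.0006047	LOC100644978	FPD/PD
A0A6P3UBL9	551	S	Heparanase	5.221	0.0251118	LOC100646845	FPD/PD
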