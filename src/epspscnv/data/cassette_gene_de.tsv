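gene_id	label	region	annotation	log2fc	p_value
EleInSChr3g081370	EPSPS	A	EPSPS	4.6	1.6e-11
EleInSChr3g081410	A410	A	Ribosomal subunit protein	5.8	2.8e-11
EleInSChr3g081390	A390	A	tRNA 2'-phosphotransferase 1	4.6	4.9e-13
EleInSChr3g081400	A400	A	Unknown protein	1.2	0.42
EleInSChr3g081440	A440	A	Unknown protein	5.2	3e-14
EleInSChr3g082510	B510	B	DNA repair protein RadA-like	5.2	6.9e-11
EleInSChr3g082560	B560	B	6-phosphofructokinase 1	0.41	0.78
EleInSChr3g082520	B520	B	Putative dual specificity protein phosphatase DSP8	1.1	0.03
EleInSChr3g082570	B570	B	E3 ubiquitin-protein ligase 1
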