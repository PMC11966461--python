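symbol	aliases	psm_cter	psm_nter	phospho	known_partner	known_sources	disease_class	disease_note	pli	correlation	is_bait
DYRK1A		97	80	Y321		 	NDD	DYRK1A syndrome	1	1	1
DCAF7		56	38		yes	a;c;d;e;f	none		0.93	0.81	0
FAM117B		21	12	S106	yes	a;c;d;f	none		0.01	0.80	0
FAM53C		13	11	S324	yes	a;c;d;e;f	none		0.07	0.12	0
PHLDB2		8	15		no		none		0	-0.31	0
GLCCI1		16	6	S30;S303	yes	a;b;c;d;e	none		0.06	0.63	0
FAM117A		15	5		yes	a;d	none		0	-0.14	0
EFHD1		5	5		no		none		0.01	-0.64	0
TRMT61B		34	0		yes	b;c	none		0	0.58	0
FN1		31	0		yes	c	other		0	-0.11	0
FGG		8	0		no		other		0	-0.17	0
PRKAR1A		8	0		yes	a;d;f	NDD	NDD and other	0.09	0.07	0
TROAP		7	1		yes	a;b;c;d	none		0	0.32	0
CYFIP2		6	1		no		NDD	DEE 65	1	0.10	0
LZTS2		6	0		yes	a;b;d;f	none		0.05	-0.49	0
CNOT1		5	0		yes	d	NDD		1	0.81	0
DHCR7		5	0		no		NDD		0	-0.04	0
GSPT1		5	0		no		none		1	0.85	0
PSMD7		5	0		no		none		0.26	0.28	0
SLC25A13		5	0		no		other		0	0.04	0
UNC119B		5	0		yes	d	other		0.78	0.22	0
SMC3		6	0		no		NDD			0.70	0
CDC42BPB		3	8		no		NDD		1	0.07	0
IGHA1		2	7		no		none			-0.34	0
NEXN		3	5		no		other		1	-0.26	0
RPA1		2	6		no		other		0	0.31	0
RNF114	ZNF313	0	19		no		none	psoriasis susceptibility locus	0.05	-0.09	0
CDC27	ANAPC3	0	18		yes	c	none		1	0.55	0
RECQL		0	10		no		other		0	0.69	0
ANAPC7		0	8		no		NDD		0.85	0.35	0
CDC23	ANAPC8	0	7		yes	c	none		0.99	0.46	0
AGO1		0	6		no		NDD		1		0
CDC16	ANAPC6	0	6		no		none		0.61	0.44	0
PRRC2B		0	6		no		none		1	0.69	0
ADAR		0	5		no		NDD		0.61	0.59	0
ANAPC4		0	5		yes	c	none		0	1	0
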