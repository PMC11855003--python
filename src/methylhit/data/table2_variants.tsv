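sample	gene	change	vaf	phase	tags	loh
ST-01	APC	R252*	0.33	unknown	-	Y
ST-01	APC	N1818fs	0.40	unknown	-	Y
ST-04	APC	E763*	0.34	unknown	-	N
ST-05	APC	R71C	0.10	unknown	V	N
ST-05	APC	S457*	0.09	unknown	-	N
ST-05	APC	T1556fs	0.04	unknown	-	N
ST-08	APC	S943*	0.59	unknown	-	Y
ST-08	APC	P1497fs	0.22	cis	C	Y
ST-08	APC	T1556fs	0.20	cis	C	Y
ST-09	APC	T1368fs	0.24	unknown	-	Y
ST-09	APC	S1415fs	0.42	unknown	-	Y
ST-11	APC	Y935fs	0.44	unknown	-	N
ST-14	APC	V452fs	0.24	unknown	-	Y
ST-14	APC	E1237*	0.34	unknown	-	Y
ST-15	APC	E1397*	0.52	unknown	-	Y
ST-16	APC	Q1367*	0.95	unknown	-	Y
ST-17	APC	L1449N	0.40	unknown	V	N
ST-20	APC	Ser1539*	0.92	unknown	-	Y
ST-25	APC	G635fs	0.15	unknown	-	N
ST-26	APC	S245*	0.62	unknown	-	Y
ST-26	APC	S2146L	0.15	unknown	V	Y
ST-27	APC	1357*	0.33	unknown	-	N
ST-29	APC	S1163_Y1166del	0.13	unknown	-	N
ST-29	APC	E1265fs	0.23	unknown	-	N
ST-29	APC	S2295_R2301del	0.10	unknown	-	N
ST-29	APC	R2347fs	0.11	unknown	-	N
ST-29	APC	S2512fs	0.11	unknown	-	N
ST-30	APC	S874*	0.35	unknown	-	Y
ST-30	APC	R1435*	0.31	unknown	-	Y
ST-31	APC	R876*	0.63	unknown	-	Y
ST-31	APC	R1450*	0.17	unknown	-	Y
ST-32	APC	R1314fs	0.91	unknown	-	Y
ST-42	APC	E901*	0.30	unknown	-	N
ST-42	APC	T1556fs	0.18	unknown	-	N
ST-46	APC	D1394fs	0.43	unknown	-	N
ST-52	APC	V1405fs	0.63	unknown	-	Y
ST-56	APC	S1421fs	0.59	unknown	-	Y
ST-56	APC	S2607F	0.29	unknown	V	Y
ST-66	APC	S1315fs	0.67	unknown	-	Y
ST-76	APC	c.835-8A>G	0.60	unknown	Sp	Y
ST-76	APC	Q2742*	0.25	unknown	-	Y
ST-01	TP53	R209Q	0.13	unknown	LO,DN	N
ST-03	TP53	Y181N	0.25	unknown	V	N
ST-04	TP53	R234H	0.51	unknown	LO,DN	Y
ST-08	TP53	R209Q	0.67	unknown	LO,DN	Y
ST-11	TP53	S176C	0.09	unknown	V	N
ST-14	TP53	E246G	0.31	unknown	V	N
ST-15	TP53	Y387fs	0.17	unknown	-	N
ST-15	TP53	Q97E	0.23	unknown	V	N
ST-16	TP53	E255fs	0.91	unknown	-	Y
ST-21	TP53	c.-32delA	0.44	unknown	-	N
ST-23	TP53	V118D	0.82	unknown	V	Y
ST-25	TP53	Ile123fs	0.06	unknown	-	N
ST-26	TP53	G206S	0.88	unknown	LO	Y
ST-27	TP53	E255G	0.33	unknown	V	N
ST-29	TP53	L383fs	0.54	unknown	-	Y
ST-29	TP53	R243W	0.14	unknown	LO,DN	Y
ST-30	TP53	R234H	0.49	trans	T,DN	Y
ST-30	TP53	R228W	0.12	trans	T	Y
ST-31	TP53	R209Q	0.86	unknown	LO,DN	Y
ST-39	TP53	V118D	0.73	unknown	V	Y
ST-40	TP53	V134L	0.43	unknown	LO	N
ST-42	TP53	Q126*	0.22	unknown	-	N
ST-46	TP53	c.258G>A T86=	0.27	unknown	Sp	N
ST-54	TP53	E17*	0.31	unknown	-	N
ST-56	TP53	G227E	0.50	unknown	V	Y
ST-66	TP53	C102Y	0.45	unknown	V	N
ST-76	TP53	Y387fs	0.645	unknown	-	Y
ST-76	TP53	R209Q	0.50	unknown	LO,DN	Y
ST-08	SMAD4	N64fs	0.66	unknown	-	Y
ST-11	SMAD4	R361C	0.12	unknown	LO	N
ST-23	SMAD4	C363R	0.77	unknown	V	Y
ST-39	SMAD4	C363R	0.81	unknown	V	Y
ST-40	SMAD4	A118V	0.35	unknown	V	N
ST-56	SMAD4	L495H	0.33	unknown	V	N
ST-76	SMAD4	C401Y	0.25	unknown	V	Y
ST-76	SMAD4	A456V	0.40	unknown	V	Y
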