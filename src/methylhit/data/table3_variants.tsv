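sample	gene	change	vaf	phase	tags	loh
ST-09	MSH2	Q893*	0.18	unknown	-	N
ST-29	MSH2	Q4*	0.25	unknown	-	N
ST-76	MSH2	N919D	0.50	unknown	V	Y
ST-29	MSH6	S625C	0.27	unknown	V	Y
ST-29	MSH6	I1170fs	0.25	unknown	-	Y
ST-76	MSH6	E807*	0.40	unknown	-	Y
ST-76	MSH6	K1315R	0.50	unknown	V	Y
ST-17	MLH1	N444fs	0.34	unknown	-	N
ST-20	MLH1	1731+2T>C	0.25	unknown	-	N
ST-25	MLH1	Q197H	0.10	unknown	V	N
ST-26	MLH1	F656C	0.09	unknown	V	N
ST-56	MLH1	M587I	0.25	unknown	V	N
ST-57	MLH1	c.306+1G>A	0.60	unknown	-	Y
ST-03	PMS2	M676V	0.42	unknown	V	N
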