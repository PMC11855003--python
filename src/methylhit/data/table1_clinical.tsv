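sample	age	sex	locus	kras	braf	msi
ST-01	62	F	T	-	-	MSS
ST-03	79	M	R	G12D	-	MSS
ST-04	55	F	S	G13D	-	MSS
ST-05	90	F	T	-	-	MSS
ST-08	86	F	C	-	-	MSS
ST-09	73	M	A	G12D	-	MSS
ST-11	67	M	R	-	-	MSS
ST-14	67	F	S	G12D	-	MSS
ST-15	80	M	C	G13D	-	MSS
ST-16	70	M	D	-	-	MSS
ST-17	84	M	A	-	V600E	MSI-H
ST-20	81	F	C	G13D	-	MSS
ST-21	64	F	S	-	-	MSS
ST-23	85	F	A	-	V600E	MSI-H
ST-25	64	M	R	-	-	MSS
ST-26	74	F	A	-	-	MSS
ST-27	77	M	D	G12D	-	MSS
ST-29	74	M	AR	-	-	MSI-H
ST-30	61	F	A	G13C	-	MSS
ST-31	84	M	A	G12V	-	MSS
ST-32	55	F	A	G12D	-	MSS
ST-39	73	F	T	-	-	MSS
ST-40	85	M	R	-	V600E	MSS
ST-42	83	F	C	G13C	-	MSS
ST-46	68	M	D	G12D	-	MSS
ST-49	82	F	A	-	V600E	MSI-H
ST-52	88	M	S	-	-	MSS
ST-54	75	M	S + T(LST)	-	-	MSS
ST-56	70	M	S + ML	-	-	MSS
ST-57	48	F	R	-	-	MSI-H
ST-66	64	F	R + LM	-	-	MSS
ST-76	59	M	S	-	-	MSS
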