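sample	gate	band
ST-01	APC_Ex1A	none
ST-01	APC_Ex1B	none
ST-01	TP53	none
ST-01	SMAD4	none
ST-01	MSH2_5UTR	none
ST-01	MSH2_In1_2	none
ST-01	MSH6	none
ST-01	MLH1	H
ST-03	APC_Ex1A	VH
ST-03	APC_Ex1B	H
ST-03	TP53	none
ST-03	SMAD4	none
ST-03	MSH2_5UTR	none
ST-03	MSH2_In1_2	none
ST-03	MSH6	none
ST-03	MLH1	EH
ST-04	APC_Ex1A	none
ST-04	APC_Ex1B	none
ST-04	TP53	none
ST-04	SMAD4	none
ST-04	MSH2_5UTR	none
ST-04	MSH2_In1_2	none
ST-04	MSH6	none
ST-04	MLH1	none
ST-05	APC_Ex1A	H
ST-05	APC_Ex1B	none
ST-05	TP53	H
ST-05	SMAD4	none
ST-05	MSH2_5UTR	none
ST-05	MSH2_In1_2	none
ST-05	MSH6	none
ST-05	MLH1	EH
ST-08	APC_Ex1A	none
ST-08	APC_Ex1B	none
ST-08	TP53	none
ST-08	SMAD4	none
ST-08	MSH2_5UTR	none
ST-08	MSH2_In1_2	none
ST-08	MSH6	none
ST-08	MLH1	none
ST-09	APC_Ex1A	none
ST-09	APC_Ex1B	none
ST-09	TP53	none
ST-09	SMAD4	none
ST-09	MSH2_5UTR	none
ST-09	MSH2_In1_2	none
ST-09	MSH6	none
ST-09	MLH1	none
ST-11	APC_Ex1A	none
ST-11	APC_Ex1B	none
ST-11	TP53	none
ST-11	SMAD4	none
ST-11	MSH2_5UTR	none
ST-11	MSH2_In1_2	none
ST-11	MSH6	none
ST-11	MLH1	none
ST-14	APC_Ex1A	EH
ST-14	APC_Ex1B	none
ST-14	TP53	none
ST-14	SMAD4	none
ST-14	MSH2_5UTR	none
ST-14	MSH2_In1_2	none
ST-14	MSH6	none
ST-14	MLH1	EH
ST-15	APC_Ex1A	none
ST-15	APC_Ex1B	none
ST-15	TP53	none
ST-15	SMAD4	none
ST-15	MSH2_5UTR	none
ST-15	MSH2_In1_2	none
ST-15	MSH6	none
ST-15	MLH1	none
ST-16	APC_Ex1A	none
ST-16	APC_Ex1B	none
ST-16	TP53	none
ST-16	SMAD4	none
ST-16	MSH2_5UTR	none
ST-16	MSH2_In1_2	none
ST-16	MSH6	none
ST-16	MLH1	none
ST-17	APC_Ex1A	none
ST-17	APC_Ex1B	none
ST-17	TP53	H
ST-17	SMAD4	none
ST-17	MSH2_5UTR	none
ST-17	MSH2_In1_2	none
ST-17	MSH6	none
ST-17	MLH1	EH
ST-20	APC_Ex1A	none
ST-20	APC_Ex1B	none
ST-20	TP53	none
ST-20	SMAD4	none
ST-20	MSH2_5UTR	none
ST-20	MSH2_In1_2	none
ST-20	MSH6	none
ST-20	MLH1	none
ST-21	APC_Ex1A	none
ST-21	APC_Ex1B	none
ST-21	TP53	none
ST-21	SMAD4	none
ST-21	MSH2_5UTR	none
ST-21	MSH2_In1_2	none
ST-21	MSH6	none
ST-21	MLH1	none
ST-23	APC_Ex1A	none
ST-23	APC_Ex1B	none
ST-23	TP53	none
ST-23	SMAD4	none
ST-23	MSH2_5UTR	none
ST-23	MSH2_In1_2	none
ST-23	MSH6	none
ST-23	MLH1	EH
ST-25	APC_Ex1A	none
ST-25	APC_Ex1B	none
ST-25	TP53	none
ST-25	SMAD4	none
ST-25	MSH2_5UTR	none
ST-25	MSH2_In1_2	none
ST-25	MSH6	none
ST-25	MLH1	none
ST-26	APC_Ex1A	none
ST-26	APC_Ex1B	none
ST-26	TP53	none
ST-26	SMAD4	none
ST-26	MSH2_5UTR	none
ST-26	MSH2_In1_2	none
ST-26	MSH6	none
ST-26	MLH1	none
ST-27	APC_Ex1A	none
ST-27	APC_Ex1B	none
ST-27	TP53	none
ST-27	SMAD4	none
ST-27	MSH2_5UTR	H
ST-27	MSH2_In1_2	H
ST-27	MSH6	H
ST-27	MLH1	none
ST-29	APC_Ex1A	none
ST-29	APC_Ex1B	none
ST-29	TP53	H
ST-29	SMAD4	none
ST-29	MSH2_5UTR	none
ST-29	MSH2_In1_2	none
ST-29	MSH6	none
ST-29	MLH1	EH
ST-30	APC_Ex1A	none
ST-30	APC_Ex1B	none
ST-30	TP53	none
ST-30	SMAD4	H
ST-30	MSH2_5UTR	none
ST-30	MSH2_In1_2	none
ST-30	MSH6	none
ST-30	MLH1	none
ST-31	APC_Ex1A	none
ST-31	APC_Ex1B	none
ST-31	TP53	none
ST-31	SMAD4	none
ST-31	MSH2_5UTR	none
ST-31	MSH2_In1_2	none
ST-31	MSH6	H
ST-31	MLH1	none
ST-32	APC_Ex1A	none
ST-32	APC_Ex1B	none
ST-32	TP53	none
ST-32	SMAD4	none
ST-32	MSH2_5UTR	H
ST-32	MSH2_In1_2	H
ST-32	MSH6	H
ST-32	MLH1	none
ST-39	APC_Ex1A	EH
ST-39	APC_Ex1B	H
ST-39	TP53	none
ST-39	SMAD4	none
ST-39	MSH2_5UTR	none
ST-39	MSH2_In1_2	H
ST-39	MSH6	none
ST-39	MLH1	none
ST-40	APC_Ex1A	H
ST-40	APC_Ex1B	none
ST-40	TP53	none
ST-40	SMAD4	none
ST-40	MSH2_5UTR	H
ST-40	MSH2_In1_2	H
ST-40	MSH6	H
ST-40	MLH1	none
ST-42	APC_Ex1A	none
ST-42	APC_Ex1B	none
ST-42	TP53	none
ST-42	SMAD4	none
ST-42	MSH2_5UTR	H
ST-42	MSH2_In1_2	none
ST-42	MSH6	H
ST-42	MLH1	none
ST-46	APC_Ex1A	none
ST-46	APC_Ex1B	none
ST-46	TP53	none
ST-46	SMAD4	none
ST-46	MSH2_5UTR	none
ST-46	MSH2_In1_2	none
ST-46	MSH6	none
ST-46	MLH1	none
ST-49	APC_Ex1A	none
ST-49	APC_Ex1B	none
ST-49	TP53	none
ST-49	SMAD4	none
ST-49	MSH2_5UTR	none
ST-49	MSH2_In1_2	none
ST-49	MSH6	none
ST-49	MLH1	VH
ST-52	APC_Ex1A	none
ST-52	APC_Ex1B	none
ST-52	TP53	none
ST-52	SMAD4	none
ST-52	MSH2_5UTR	none
ST-52	MSH2_In1_2	none
ST-52	MSH6	none
ST-52	MLH1	EH
ST-54	APC_Ex1A	none
ST-54	APC_Ex1B	none
ST-54	TP53	none
ST-54	SMAD4	none
ST-54	MSH2_5UTR	none
ST-54	MSH2_In1_2	none
ST-54	MSH6	none
ST-54	MLH1	none
ST-56	APC_Ex1A	VH
ST-56	APC_Ex1B	none
ST-56	TP53	none
ST-56	SMAD4	none
ST-56	MSH2_5UTR	none
ST-56	MSH2_In1_2	none
ST-56	MSH6	none
ST-56	MLH1	H
ST-57	APC_Ex1A	none
ST-57	APC_Ex1B	none
ST-57	TP53	none
ST-57	SMAD4	none
ST-57	MSH2_5UTR	none
ST-57	MSH2_In1_2	none
ST-57	MSH6	none
ST-57	MLH1	none
ST-66	APC_Ex1A	EH
ST-66	APC_Ex1B	none
ST-66	TP53	none
ST-66	SMAD4	none
ST-66	MSH2_5UTR	H
ST-66	MSH2_In1_2	none
ST-66	MSH6	none
ST-66	MLH1	none
ST-76	APC_Ex1A	H
ST-76	APC_Ex1B	none
ST-76	TP53	none
ST-76	SMAD4	none
ST-76	MSH2_5UTR	none
ST-76	MSH2_In1_2	none
ST-76	MSH6	none
ST-76	MLH1	none
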