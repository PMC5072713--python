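# Codon usage of the Utricularia reniformis plastome protein-coding repertoire
# (22,601 codons), with the published RSCU / within-family percentage columns and
# the codon -> tRNA (anticodon) recognition assignments.
aa	codon	count	rscu_printed	family_pct_printed	trna
Ala	GCU	479	1.64	40.9	-
Ala	GCC	201	0.69	17.2	-
Ala	GCA	346	1.18	29.6	trnA-UGC
Ala	GCG	143	0.49	12.3	-
Cys	UGU	181	1.49	74.4	-
Cys	UGC	62	0.51	25.6	trnC-GCA
Asp	GAU	702	1.60	79.9	-
Asp	GAC	176	0.40	20.1	trnD-GUC
Glu	GAA	878	1.50	74.9	trnE-UUC
Glu	GAG	294	0.50	25.1	-
Phe	UUU	806	1.31	65.4	-
Phe	UUC	426	0.69	35.6	trnF-GAA
Gly	GGU	483	1.27	31.7	-
Gly	GGC	184	0.48	12.2	trnG-GCC
Gly	GGA	555	1.46	36.4	trnG-UCC
Gly	GGG	300	0.79	19.7	-
His	CAU	420	1.49	74.6	-
His	CAC	142	0.51	25.4	trnH-GUG
Ile	AUU	916	1.50	49.9	-
Ile	AUC	369	0.60	20.1	trnI-GAU
Ile	AUA	548	0.90	30	trnI-CAU
Lys	AAA	990	1.48	73.9	trnK-UUU
Lys	AAG	348	0.52	26.1	-
Leu	UUA	704	1.82	30.3	trnL-UAA
Leu	UUG	493	1.27	21.2	trnL-CAA
Leu	CUU	501	1.29	21.5	-
Leu	CUC	148	0.38	6.3	-
Leu	CUA	312	0.80	13.4	trnL-UAG
Leu	CUG	168	0.43	7.3	-
Met	AUG	480	1.00	100	trnfM-CAU
Asn	AAU	843	1.49	74.6	-
Asn	AAC	287	0.51	25.4	trnN-GUU
Pro	CCU	339	1.42	35.6	-
Pro	CCC	214	0.90	22.4	-
Pro	CCA	240	1.01	25.2	trnP-UGG
Pro	CCG	159	0.67	16.8	-
Gln	CAA	629	1.51	75.3	trnQ-UUG
Gln	CAG	206	0.49	24.7	-
Arg	CGU	301	1.24	20.7	trnR-ACG
Arg	CGC	115	0.47	7.9	-
Arg	CGA	338	1.39	23.3	-
Arg	CGG	128	0.53	8.7	-
Arg	AGA	407	1.68	27.9	trnR-UCU
Arg	AGG	168	0.69	11.5	-
Ser	UCU	475	1.67	27.8	-
Ser	UCC	275	0.97	16.1	trnS-GGA
Ser	UCA	320	1.12	18.7	trnS-UGA
Ser	UCG	198	0.70	11.6	-
Ser	AGU	345	1.21	20.2	-
Ser	AGC	95	0.33	5.6	trnS-GCU
Thr	ACU	464	1.54	38.3	-
Thr	ACC	234	0.77	19.4	trnT-GGU
Thr	ACA	366	1.21	30.3	trnT-UGU
Thr	ACG	144	0.48	12	-
Val	GUU	457	1.46	36.5	-
Val	GUC	163	0.52	13.1	trnV-GAC
Val	GUA	466	1.49	37.2	trnV-UAC
Val	GUG	166	0.53	13.2	-
Tyr	UAU	642	1.52	76	-
Tyr	UAC	202	0.48	24	trnY-GUA
Trp	UGG	384	1.00	100	trnW-CCA
Stop	UGA	16	0.63	21	-
Stop	UAA	39	1.54	51	-
Stop	UAG	21	0.83	27	-
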