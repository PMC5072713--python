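# Transfer-RNA genes annotated on the Utricularia reniformis plastome.
# copies = gene copy number (2 for genes duplicated in the inverted repeats).
name	anticodon	copies
trnA-UGC	UGC	2
trnC-GCA	GCA	1
trnD-GUC	GUC	1
trnE-UUC	UUC	1
trnF-GAA	GAA	1
trnG-GCC	GCC	1
trnG-UCC	UCC	1
trnH-GUG	GUG	1
trnI-CAU	CAU	2
trnI-GAU	GAU	2
trnK-UUU	UUU	1
trnL-CAA	CAA	2
trnL-UAA	UAA	1
trnL-UAG	UAG	1
trnM-CAU	CAU	1
trnN-GUU	GUU	2
trnP-UGG	UGG	1
trnQ-UUG	UUG	1
trnR-ACG	ACG	2
trnR-UCU	UCU	1
trnS-GCU	GCU	1
trnS-GGA	GGA	1
trnS-UGA	UGA	1
trnT-GGU	GGU	1
trnT-UGU	UGU	1
trnV-GAC	GAC	2
trnV-UAC	UAC	1
trnW-CCA	CCA	1
trnY-GUA	GUA	1
trnfM-CAU	CAU	1
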