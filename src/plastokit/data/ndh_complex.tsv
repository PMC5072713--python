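# ndh gene complex across eight Lamiales plastomes (long format).
# status: intact | pseudogene | absent. length_bp is the annotated locus length
# (blank for absent loci). ir_copies = 2 where the locus is duplicated in the
# inverted repeats (ndhB everywhere it is present; ndhF only in U. gibba).
# region: plastome region hosting the locus in U. reniformis relatives.
taxon	gene	region	status	length_bp	ir_copies
Sesamum_indicum	ndhA	SSC	intact	2171	1
Sesamum_indicum	ndhB	IR	intact	2211	2
Sesamum_indicum	ndhC	LSC	intact	362	1
Sesamum_indicum	ndhD	SSC	intact	1502	1
Sesamum_indicum	ndhE	SSC	intact	305	1
Sesamum_indicum	ndhF	SSC	intact	2255	1
Sesamum_indicum	ndhG	SSC	intact	530	1
Sesamum_indicum	ndhH	SSC	intact	1181	1
Sesamum_indicum	ndhI	SSC	intact	506	1
Sesamum_indicum	ndhJ	LSC	intact	476	1
Sesamum_indicum	ndhK	LSC	intact	701	1
Tanaecium_tetragonolobum	ndhA	SSC	intact	2162	1
Tanaecium_tetragonolobum	ndhB	IR	intact	2211	2
Tanaecium_tetragonolobum	ndhC	LSC	intact	362	1
Tanaecium_tetragonolobum	ndhD	SSC	pseudogene	1148	1
Tanaecium_tetragonolobum	ndhE	SSC	intact	305	1
Tanaecium_tetragonolobum	ndhF	SSC	intact	2231	1
Tanaecium_tetragonolobum	ndhG	SSC	intact	530	1
Tanaecium_tetragonolobum	ndhH	SSC	intact	1181	1
Tanaecium_tetragonolobum	ndhI	SSC	intact	506	1
Tanaecium_tetragonolobum	ndhJ	LSC	intact	476	1
Tanaecium_tetragonolobum	ndhK	LSC	intact	677	1
Andrographis_paniculata	ndhA	SSC	intact	2069	1
Andrographis_paniculata	ndhB	IR	intact	2211	2
Andrographis_paniculata	ndhC	LSC	intact	362	1
Andrographis_paniculata	ndhD	SSC	intact	1454	1
Andrographis_paniculata	ndhE	SSC	intact	305	1
Andrographis_paniculata	ndhF	SSC	intact	2231	1
Andrographis_paniculata	ndhG	SSC	intact	530	1
Andrographis_paniculata	ndhH	SSC	intact	1181	1
Andrographis_paniculata	ndhI	SSC	intact	506	1
Andrographis_paniculata	ndhJ	LSC	intact	476	1
Andrographis_paniculata	ndhK	LSC	intact	677	1
Pinguicula_ehlersiae	ndhA	SSC	pseudogene	1811	1
Pinguicula_ehlersiae	ndhB	IR	intact	2211	2
Pinguicula_ehlersiae	ndhC	LSC	absent		0
Pinguicula_ehlersiae	ndhD	SSC	pseudogene	622	1
Pinguicula_ehlersiae	ndhE	SSC	pseudogene	309	1
Pinguicula_ehlersiae	ndhF	SSC	absent		0
Pinguicula_ehlersiae	ndhG	SSC	pseudogene	520	1
Pinguicula_ehlersiae	ndhH	SSC	pseudogene	1131	1
Pinguicula_ehlersiae	ndhI	SSC	pseudogene	514	1
Pinguicula_ehlersiae	ndhJ	LSC	pseudogene	434	1
Pinguicula_ehlersiae	ndhK	LSC	pseudogene	410	1
Genlisea_margaretae	ndhA	SSC	pseudogene	197	1
Genlisea_margaretae	ndhB	IR	pseudogene	2121	2
Genlisea_margaretae	ndhC	LSC	absent		0
Genlisea_margaretae	ndhD	SSC	absent		0
Genlisea_margaretae	ndhE	SSC	pseudogene	188	1
Genlisea_margaretae	ndhF	SSC	absent		0
Genlisea_margaretae	ndhG	SSC	absent		0
Genlisea_margaretae	ndhH	SSC	absent		0
Genlisea_margaretae	ndhI	SSC	pseudogene	469	1
Genlisea_margaretae	ndhJ	LSC	absent		0
Genlisea_margaretae	ndhK	LSC	absent		0
Utricularia_reniformis	ndhA	SSC	pseudogene	1640	1
Utricularia_reniformis	ndhB	IR	pseudogene	1080	2
Utricularia_reniformis	ndhC	LSC	absent		0
Utricularia_reniformis	ndhD	SSC	pseudogene	737	1
Utricularia_reniformis	ndhE	SSC	pseudogene	233	1
Utricularia_reniformis	ndhF	SSC	absent		0
Utricularia_reniformis	ndhG	SSC	pseudogene	509	1
Utricularia_reniformis	ndhH	SSC	pseudogene	1085	1
Utricularia_reniformis	ndhI	SSC	pseudogene	520	1
Utricularia_reniformis	ndhJ	LSC	absent		0
Utricularia_reniformis	ndhK	LSC	absent		0
Utricularia_macrorhiza	ndhA	SSC	intact	2190	1
Utricularia_macrorhiza	ndhB	IR	intact	2211	2
Utricularia_macrorhiza	ndhC	LSC	intact	362	1
Utricularia_macrorhiza	ndhD	SSC	intact	1526	1
Utricularia_macrorhiza	ndhE	SSC	intact	305	1
Utricularia_macrorhiza	ndhF	SSC	intact	2261	1
Utricularia_macrorhiza	ndhG	SSC	intact	530	1
Utricularia_macrorhiza	ndhH	SSC	intact	1187	1
Utricularia_macrorhiza	ndhI	SSC	intact	530	1
Utricularia_macrorhiza	ndhJ	LSC	intact	476	1
Utricularia_macrorhiza	ndhK	LSC	intact	644	1
Utricularia_gibba	ndhA	SSC	intact	2153	1
Utricularia_gibba	ndhB	IR	intact	2211	2
Utricularia_gibba	ndhC	LSC	intact	362	1
Utricularia_gibba	ndhD	SSC	intact	1526	1
Utricularia_gibba	ndhE	SSC	intact	305	1
Utricularia_gibba	ndhF	SSC	intact	2261	2
Utricularia_gibba	ndhG	SSC	intact	530	1
Utricularia_gibba	ndhH	SSC	intact	1181	1
Utricularia_gibba	ndhI	SSC	intact	524	1
Utricularia_gibba	ndhJ	LSC	intact	476	1
Utricularia_gibba	ndhK	LSC	intact	677	1
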