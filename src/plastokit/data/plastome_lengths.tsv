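# Plastome lengths (bp) of the eight taxa used in the ndh-complex comparison;
# deposited reference sequence lengths.
taxon	genome_bp
Sesamum_indicum	153324
Tanaecium_tetragonolobum	153776
Andrographis_paniculata	150249
Pinguicula_ehlersiae	147140
Genlisea_margaretae	141252
Utricularia_reniformis	139725
Utricularia_macrorhiza	153228
Utricularia_gibba	152044
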