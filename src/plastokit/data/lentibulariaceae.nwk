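(Sesamum_indicum,(Tanaecium_tetragonolobum,(Andrographis_paniculata,(Pinguicula_ehlersiae,(Genlisea_margaretae,(Utricularia_reniformis,(Utricularia_macrorhiza,Utricularia_gibba)))))));
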