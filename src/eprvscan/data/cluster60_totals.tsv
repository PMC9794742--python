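otu	printed_n_seqs
Badnavirus	80
Caulimovirus	38
Dioscovirus	144
Petuvirus	1693
Solendovirus	1124
Soymovirus	454
Tungrovirus	308
Florendovirus	6162
Gymnendovirus	95
Wendovirus	282
Xendovirus	65
Yendovirus	334
Zendovirus	781
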