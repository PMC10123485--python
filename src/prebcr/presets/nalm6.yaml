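# Nalm6 B-ALL cell line: slow dimer dissociation, high Syk abundance.
cell_line_label: nalm6
n_syk_cell: 274302
k_off_dimer: 0.159
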