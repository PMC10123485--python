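# 697 B-ALL cell line: fast dimer dissociation, lower Syk abundance.
cell_line_label: "697"
n_syk_cell: 48290
k_off_dimer: 1.14
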