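# Shared pre-B cell geometry, diffusion and simulation-protocol constants.
# Units: lengths um, times s, diffusion um^2/s, rates /s.
cell_line_label: base
n_receptors_cell: 10000
n_syk_cell: 48290
lyn_fraction: 0.10
d_rec: 0.16
d_lyn: 0.4
d_syk: 17.0
sigma_rec: 1.0e-4
k_off_dimer: 1.14
cell_area: 315.7
cell_volume: 321.8
box_x: 1.5
box_y: 1.5
box_z: 0.5
dt: 1.0e-5
t_total: 600.0
t_ini: 50.0
exit_probability: 0.2
sample_interval: 0.1
seed: 0
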