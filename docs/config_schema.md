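# Configuration schema

Configurations are YAML mappings (see `src/prebcr/presets/`). Unknown keys
are rejected; `cell_line_label`, `n_receptors_cell`, `n_syk_cell` and
`k_off_dimer` are required, everything else defaults as below.

| key | unit | default | meaning |
|---|---|---|---|
| `cell_line_label` | — | — | condition name ("697", "nalm6", ...) |
| `n_receptors_cell` | count | 10000 | pre-BCR per cell; scaled to the box by area |
| `n_syk_cell` | count | 48290 | Syk per cell (274302 for Nalm6); scaled by volume |
| `lyn_fraction` | — | 0.10 | Lyn pool available to receptors, as a fraction of receptors |
| `d_rec` | μm²/s | 0.16 | monomeric receptor diffusion coefficient |
| `d_lyn` | μm²/s | 0.4 | Lyn diffusion coefficient |
| `d_syk` | μm²/s | 17.0 | Syk diffusion coefficient (3-D) |
| `sigma_rec` | μm | 1.0e-4 | receptor–receptor binding radius (calibrated at dt = 1e-5 s) |
| `k_off_dimer` | /s | 1.14 | per-bond dissociation rate (0.159 for Nalm6) |
| `cell_area` | μm² | 315.7 | whole-cell membrane area |
| `cell_volume` | μm³ | 321.8 | whole-cell cytosolic volume |
| `box_x`, `box_y` | μm | 1.5 | membrane patch dimensions (periodic) |
| `box_z` | μm | 0.5 | cytosol depth (reflective) |
| `dt` | s | 1.0e-5 | time step |
| `t_total` | s | 600.0 | total simulated time |
| `t_ini` | s | 50.0 | equilibration window excluded from averages |
| `exit_probability` | — | 0.2 | per-crossing microdomain escape probability |
| `sample_interval` | s | 0.1 | observable sampling cadence |
| `seed` | int | 0 | base RNG seed (replicate i uses seed + i) |
| `lyn_table` | μm, /s | Lyn binding table | per (ITAM kind, status): radius, off_rate, mode |
| `syk_table` | μm, /s | Syk binding table | per (ITAM kind, status): radius, off_rate |
| `phospho_table` | /s | kinase rate table | itam [activated][site], lyn_y397, syk_linker, syk_catalytic |
| `dephospho_table` | /s | dephospho table | itam {1,2}, lyn_y397, syk |

The four rate tables default to the values in `prebcr.molecules` (the
binding radii/off-rates and phosphorylation/dephosphorylation rates listed
in `docs/methods.md`); override any subset in YAML using the same nesting
as `prebcr.model_config.default_rate_tables()`.
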