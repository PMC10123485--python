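"""Scale whole-cell molecule counts to the simulation box.

The box is a 1.5 x 1.5 um patch of membrane with 0.5 um of cytosol below.
Counts scale by area (membrane species) or volume (cytosolic species)
against the morphometric cell estimates.
"""

from prebcr import get_preset

for name in ("697", "nalm6"):
    p = get_preset(name)
    print(f"{name}: {p.n_receptors_box} receptors, {p.n_lyn_box} Lyn, "
          f"{p.n_syk_box} Syk in the {p.box_x}x{p.box_y}x{p.box_z} um box "
          f"(k_off = {p.k_off_dimer}/s)")
print(f"receptor density: {10000 / 315.7:.1f} per um^2")

# Expected output: 71 receptors and 7 Lyn for both lines; 169 Syk for 697
# vs 959 for Nalm6 (5.7x the Syk abundance); density ~32 receptors/um^2.
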