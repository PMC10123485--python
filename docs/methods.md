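# Methods

`prebcr` simulates ligand-independent ("tonic") signal initiation by the
pre-B cell receptor (pre-BCR) on the membrane of precursor B cells. It is a
lattice-free, agent- and rule-based stochastic model: every copy of the
three base species — the divalent pre-BCR, the Src-family kinase Lyn, and
the cytosolic kinase Syk — is an individual particle with continuous
coordinates and a discrete internal state.

## Model

**Geometry.** The simulation space is a rectangular cuboid: a 1.5 × 1.5 μm
patch of plasma membrane (periodic in x and y) with 0.5 μm of cytosol below
(reflective in z). Receptors and Lyn live in the membrane plane; Syk
diffuses in three dimensions and docks at the membrane (z = 0) when bound.
Whole-cell copy numbers (10,000 receptors; 48,290 or 274,302 Syk for the
697 and Nalm6 cell lines; a Lyn pool of 10% of receptors) are scaled to the
box by the area ratio against the 315.7 μm² cell surface or the volume
ratio against the 321.8 μm³ cytosol, with nearest-integer rounding, giving
71 receptors, 7 Lyn, and 169 or 959 Syk. The box volume is taken as the
geometric product 1.5 × 1.5 × 0.5 = 1.125 μm³; this is the value consistent
with the scaled Syk counts.

**Diffusion.** Each free molecule takes independent Gaussian jumps per
coordinate with RMS √(2 D Δt). A receptor chain of M members moves as one
point with D_agg = D_rec / M. Defaults: D_rec = 0.16 μm²/s, D_Lyn =
0.4 μm²/s, D_Syk = 17 μm²/s, Δt = 10⁻⁵ s. Bound kinases co-move with their
receptor's chain.

**Oligomerization.** Receptors are divalent and form strictly linear chains
(no rings). Two chains merge when their points come within the receptor
binding radius σ_B (default 10⁻⁴ μm, calibrated against the well-mixed
model at Δt = 10⁻⁵ s); each receptor–receptor bond breaks with per-step
probability 1 − exp(−k_off Δt), where k_off is 1.14/s (697) or 0.159/s
(Nalm6).

**Signaling rules.** Each receptor carries one lumped Igα site and one
lumped Igβ site with phosphorylation status 0/1/2 and a single occupancy
slot. Lyn binds unphosphorylated Igα via its unique domain (radius
2.29 × 10⁻⁴ μm, off 20/s) and phosphorylated Igα/Igβ via its SH2 domain
(off 0.12/s; the Igβ radius is half the Igα radius). Syk docks only on
phosphorylated ITAMs; its radius is larger and its off-rate lower on doubly
phosphorylated sites (0.3/s vs 2.6/s), and its Igβ radii are one third of
the Igα radii. All phosphorylation is strictly *trans*: a docked kinase
acts only on substrates of the immediately adjacent receptors in its chain
— monomers never signal. Unactivated Lyn phosphorylates ITAM sites at
30/s (first site) and 15/s (second); Lyn activated at Y397 works at
100/50 per s, and the same pair of rate sets applies to Lyn→Lyn(Y397) and
Lyn→Syk-linker (30 vs 100/s). Syk phosphorylates the Syk catalytic site of
a neighbour-docked Syk at 100/s, or 200/s when itself catalytically
phosphorylated. Dephosphorylation is first-order and unconditional:
ITAMs step down 2→1 at 40/s and 1→0 at 20/s; Lyn Y397 and both Syk sites
at 20/s. The rate table prints no Syk dephosphorylation entries and no
Igβ rows for unactivated Lyn; we adopt the symmetric completion (Syk sites
at 20/s; the {30,15}/{100,50} ITAM rates apply to both Igα and Igβ), which
matches the stated ~3× activity gain on activation.

**Microdomains.** The membrane carries closed polygonal contours that
confine receptors: entry is unimpeded, but a jump crossing the contour from
inside escapes only with probability 0.2 per crossing attempt and is
otherwise reflected specularly about the crossed edge (repeatedly if the
reflected remainder exits again). Only receptors/aggregates observe
domains; Lyn and Syk ignore them, enforced structurally in the propagation
kernel. Domains are static within a run.

**Step order.** Each step applies first-order events (trans-phosphorylation,
dephosphorylation, kinase release, bond breaking), then diffusion with
boundary/domain handling, then collision detection and binding. The order
is a fixed implementation constant chosen so a newly formed pair survives
at least one step; at the default Δt all per-step probabilities are ≤ 10⁻³,
so order effects are second order. Within binding, candidate events are
processed in uniformly shuffled order, one binding per molecule per step,
with stale candidates skipped. Merged chains randomize their end
orientation (adjacency is symmetric, so observables are unaffected).

## Numerical choices

- Released partners (after bond breaking or kinase release) are placed
  1.1 × the relevant binding radius apart along a uniformly random
  direction (3-D for Syk, into the cytosol), preventing deterministic
  instant re-binding. The factor 1.1 is a documented constant.
- A kinase can remain docked while its site is dephosphorylated beneath it;
  the tables list no off-rate for those states, so it releases fast:
  20/s for Lyn on Igβ status 0, 2.6/s for Syk on a status-0 ITAM (the
  phospho-tyrosine holding the SH2 contact is gone).
- Pair distances use the minimum-image convention in x and y.
- σ_B and Δt were calibrated jointly; changing Δt while keeping the default
  σ_B triggers a warning that re-calibration is needed.
- The averaging window defaults to [t_ini, t_total] with t_ini = 50 s at
  full scale; scaled-down runs use proportionally shorter windows.
- Structural invariants (path topology, occupancy exclusivity, positions
  in the box, conservation) are re-checked every 10⁴ steps; continuous
  checking would dominate runtime.
- One seeded PCG64 generator drives a run; replicate seeds are derived as
  seed + replicate index and recorded in the run manifest.
- The hot loop is numba-compiled over flat arrays; the per-operation API
  (`propagate`, `fire_first_order`, `detect_and_bind`) calls the same
  compiled kernels as the fused run loop, so there is a single logic path.

## Well-mixed oracle and binding-radius calibration

The well-mixed module simulates the same linear-chain aggregation without
space: any two chains associate at a per-pair rate k_on and any bond breaks
at k_off, sampled exactly (event-driven, exponential waiting times), so it
carries no time-discretization error. Association is size-independent per
chain pair, the simplest kernel consistent with a single effective on-rate;
a diffusion-weighted kernel would be a straightforward extension. k_on is a
required input and is never defaulted: it is an effective volume-scaled
rate that must be estimated externally or measured from the spatial engine
(merge events per pair-step). Calibration sweeps the spatial engine's
binding radius over a grid (the historical sweep covered 5 × 10⁻⁵ to
3.5 × 10⁻⁴ μm) in a domain-free box and selects the radius minimizing the
L1 distance between the receptor-weighted {monomer, dimer, ≥trimer}
fractions and the well-mixed target.

In the domain-free case the two models agree quantitatively when the
well-mixed k_on is set to the spatial engine's measured per-pair
encounter-and-bind rate (L1 distance ~0.01–0.08 at N = 30), and the
two-receptor system reproduces the two-state closed form
k_on/(k_on + k_off) for dimer occupancy — this is the engine's primary
correctness oracle.

## Domain reconstruction from SPT

The reconstruction mirrors a trajectory-based domain-mapping procedure:
for every trajectory point, jump sizes over a set of time lags are
computed; a point is *slow* (confined) if it falls below a quantile
threshold of the pooled jump-size distribution for every lag; slow points
are clustered by single linkage with linking distance L; clusters of at
least a minimum size with ≥ 3 distinct positions are contoured by their
convex hull. The lag set, threshold quantile (default 0.5), L, and minimum
cluster size are configuration parameters with documented defaults — the
original analysis pipeline does not publish them, so these are this
package's own choices, not claims about that pipeline. The convex hull is
one of several reasonable contouring strategies (an alpha shape would trace
concave domains more tightly); it is kept swappable.

## Synthetic data

Two generators provide ground-truth fixtures:

- `generate_synthetic_domains` places non-overlapping regular polygons
  (disk approximations) uniformly at random. Study-condition runs use 12
  domains with radii 0.08–0.15 μm (~20–25% of the membrane area), a density
  at which confinement measurably promotes aggregation while leaving most
  of the membrane free.
- `generate_synthetic_spt` produces Brownian tracks obeying the same
  confinement kernel as the engine, with per-point ground-truth domain
  membership retained for recovery scoring. Its box boundary is
  *reflective*, not periodic: a microscope field of view is not periodic,
  and wrap-around jumps would corrupt the jump-size statistics the
  reconstruction relies on.

What the synthetic fixtures do not emulate: localization noise, blinking
and gaps in real SPT tracks, irregular (non-convex, mobile) domain shapes,
and heterogeneous per-cell expression levels. Passing recovery tests
therefore demonstrates the reconstruction logic, not field performance on
microscope data.

## Scaled-down protocols

The full study protocol (T = 600 s, t_ini = 50 s, three replicates per
condition) is hours of compute per condition at Δt = 10⁻⁵ s. The test
suite and the acceptance script run scaled-down replicas: T = 20 s with
t_ini = 5 s and one replicate per condition — enough for the qualitative
orderings (Nalm6 aggregates more than 697; domains promote aggregation in
both) to be stable, while absolute steady-state percentages remain further
from equilibrium than at full scale, particularly for Nalm6 whose bond
lifetime is 6.3 s. Oracle checks use denser scaled boxes (0.5 × 0.5 μm,
N = 2–30, larger σ_B, Δt = 10⁻⁴ s) where aggregation statistics converge
in ~1 minute of simulated time; both sides of each comparison are measured
under the same conditions, so the scaling does not bias the check.

## Known limitations

- Aggregates are represented by a single point; internal chain geometry,
  rotational diffusion, and steric effects are not modeled.
- No explicit phosphatase: dephosphorylation is first-order with no
  shielding of occupied sites.
- No receptor internalization, synthesis, degradation, or ligand
  engagement; copy numbers are conserved for a run.
- Fixed-Δt Brownian stepping with a binding radius (Smoluchowski-style);
  binding radii are calibrated for Δt = 10⁻⁵ s and do not transfer to other
  time steps without re-calibration.
- A population is simulated as one homogeneous parameter set per cell
  line; cell-to-cell expression heterogeneity is out of scope.
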