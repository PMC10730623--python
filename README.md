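# chorioflow

Image-based computational hemodynamics of the human choriocapillaris — the
planar, anastomotic capillary bed of the inner choroid that supplies the
photoreceptors and retinal pigment epithelium.  Starting from a binary
en-face capillary mask (lumen = 1, intercapillary pillar = 0) and a map of
the arteriole/venule junctions of Sattler's layer, the package builds a
3-D flow domain, solves steady pressure-driven blood flow with a
volumetric lattice Boltzmann method (VLBM), and derives the quantities
that characterize perfusion: velocity and pressure fields, endothelial
shear stress (ESS), arteriole-to-venule transit-time distributions,
functional lobule maps, and anatomy-perturbation experiments that probe
how capillary density and junction arrangement shape flow — the changes
seen in aging and age-related macular degeneration.

## The model in brief

Geometry is encoded per lattice cell by the solid volume fraction
P ∈ [0, 1] (solid 1, fluid 0, boundary in between).  The VLBM evolves
particle populations n_i = (1 − P) f_i by BGK collision toward

  n_i^eq = N w_i [1 + e_i·u/c_s² + (e_i·u)²/2c_s⁴ − u·u/2c_s²],

followed by volumetric streaming: pulls across cells of unequal solidity
are rescaled by the fluid-volume ratio or partially bounced back by the
solidity jump, which enforces no-slip in boundary cells and conserves
mass exactly for arbitrary fractional P.  Macroscopic fields are
ρ = Σn_i/(1 − P), u = Σe_i n_i/Σn_i, p − p₀ = c_s²(ρ − ρ₀).  Blood is
Newtonian (ρ = 1060 kg/m³, ν = 3.8×10⁻⁶ m²/s); arteriole inlets and
venule outlets carry 44.2 / 35.6 mmHg; lateral boundaries are periodic.

The wall traction follows from the total stress
T = −(Σn_i c_s²/(1 − P)) δ + (2τ − 1) c_s² S, with the strain rate S
taken from the second moment of the non-equilibrium populations (or by
finite differences); the Cauchy traction T·N splits into endothelial
normal stress and ESS.  An independent Hele-Shaw potential-flow solver
(point sources/sinks in a thin gap, free-space or periodic-spectral
kernel) provides reference solutions for open-plane layouts, against
which the lattice solver's transit-time PDFs are validated.

Full formulation, numerical choices and limitations: `docs/methods.md`.

## Worked example

Synthesize a donor-like capillary mask, check its anatomy, and apply two
of the capillary permutations:

```python
from chorioflow import (generate_synthetic_mask, permute_capillaries,
                        PermutationSpec, capillary_density,
                        mean_capillary_diameter)

mask = generate_synthetic_mask(500, 500, target_density=74.4, seed=11)
print(f"density   {capillary_density(mask):.1f} %")
print(f"diameter  {mean_capillary_diameter(mask):.1f} um")
opened = permute_capillaries(mask, PermutationSpec(mode="open"))
shrunk = permute_capillaries(mask, PermutationSpec(mode="constricted"))
print(f"open        {capillary_density(opened):.1f} %")
print(f"constricted {capillary_density(shrunk):.1f} %")
```

prints

```
density   74.4 %
diameter  20.1 um
open        100.0 %
constricted 68.8 %
```

— a 0.25 mm² anastomotic plane at the donor-range density and mean
capillary diameter; opening removes every pillar (density 100%), while
growing each pillar radially by 2.5 µm constricts the capillaries and
lowers the density.

The packaged donor tables (eight cases) reproduce the published
cross-case averages, weighted by analyzed tissue area:

```
$ chorioflow summarize --table weighted
area-weighted mean velocity (mm/s): 1.73
area-weighted mean ESS (Pa): 1.69
area-weighted mean P^Art - P (mmHg): 7.36
```

A full simulation pipeline runs from the command line —
`chorioflow build-geometry`, `simulate`, `stress`, `trace`,
`validate-oracle`, `summarize`, `report` — or from Python via
`run_to_steady`, `wall_stress`, `trace_particles` and friends.

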