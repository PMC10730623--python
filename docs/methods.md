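# Methods

## The physical model

The choriocapillaris is treated as a thin, planar, highly anastomotic
capillary bed: a gap of thickness ~10 µm interrupted by avascular
intercapillary pillars, fed and drained from the posterior side by
arteriole and venule junctions of Sattler's layer.  Blood is modelled as a
homogeneous Newtonian fluid (density 1060 kg/m³, kinematic viscosity
3.8×10⁻⁶ m²/s); walls are rigid; flow is steady (no pulsatility).  A
constant pressure pair drives perfusion — 44.2 mmHg at every arteriole
inlet and 35.6 mmHg at every venule outlet — values calibrated so that
mean capillary blood velocity falls in the physiologic ~1.5 mm/s range on
donor-scale anatomies.  The lateral domain boundaries are periodic.

## Volumetric lattice Boltzmann solver (`engine`, `lattice`)

The solver evolves per-cell particle populations n_i(x, t) on a D3Q19
lattice (a D2Q9 model, embedded with e_z = 0, is available for plane
benchmarks).  Geometry enters through the solid volume fraction
P(x) ∈ [0, 1] per cell: solid (P = 1), fluid (P = 0), and boundary cells
(0 < P < 1).  Populations relate to the node-based distribution by
n_i = (1 − P) f_i, so the scheme reduces to standard LBM in fluid cells.

One step is BGK collision followed by volumetric streaming:

* **Collision** relaxes toward the incompressible equilibrium
  n_i^eq = N w_i {1 + e·u/c_s² + (e·u)²/(2c_s⁴) − u²/(2c_s²)} built from
  the cell's own moments N = Σ n_i and u = Σ e n_i / N, with forcing
  F_i = −w_i N (e_i·a)/c_s² δt.  With this sign convention the momentum
  injected per step is −N a, so drivers pass a = −g to push flow along g.
* **Streaming** is a gather along the reverse direction.  When the upwind
  neighbour is strictly less solid, the pulled population is rescaled by
  the fluid-volume ratio (1 − P(x))/(1 − P(x_up)); otherwise the plain
  pull is augmented by a volumetric bounce-back of the cell's own
  opposite post-collision population weighted by the solidity jump.  The
  two branches are exclusive; summed over any adjacent pair the scheme
  conserves mass identically for arbitrary fractional P (verified to
  10⁻¹² relative over hundreds of steps in the tests).  Against sharp
  walls the rule reduces to half-way bounce-back, giving second-order
  accurate channel flow (the Poiseuille benchmark at 32 cells is within
  1%, and the error falls by more than 2.5× on refinement from 16 cells).

Macroscopic fields are ρ = Σ n_i/(1 − P), u = Σ e n_i / Σ n_i and
p − p₀ = c_s²(ρ − ρ₀) with ρ₀ = 1 anchored at the venule outlets.

**Units.**  The time step follows diffusive scaling:
dt = c_s²(τ − ½) dx²/ν.  Velocity converts by dx/dt, pressure and stress
by ρ_phys (dx/dt)².  Default τ = 1.0 for production runs (τ = 0.8
elsewhere): at the 4–5 µm cell sizes used here this keeps the lattice
Mach number of capillary flow below ~0.06 while allowing a practical time
step.

**Pressure boundaries.**  Junction tubes are carved through the posterior
cap and extended ~35 µm; their end faces prescribe density
ρ = ρ₀ + Δp_lat/c_s² by non-equilibrium extrapolation (equilibrium at the
target density with the adjacent interior cell's velocity, plus that
cell's non-equilibrium part).  Only fully open (P = 0) face cells are
prescribed; fractional rim columns stay under the volumetric dynamics.
Junction fluxes are measured as mass flux over the full tube
cross-section, normalized by the reference density so that inlet and
outlet fluxes balance despite the slight face-density offset of the
weakly compressible scheme.

**Steady state.**  Runs stop when the relative L2 change of the velocity
field over 100–200 steps falls below a tolerance (10⁻⁶ by default; the
larger multi-run experiments use 10⁻⁵–2×10⁻⁶, where the residual slow
mode contributes less than ~10⁻⁴ relative field error, far below the
sampling noise of the transit statistics computed from the fields).  A
2-D Laplace interpolation of the junction pressures (periodic five-point
stencil, Dirichlet discs) seeds the initial density; this shortens the
acoustic transient and cannot change the fixed point.

## Geometry construction (`geometry`)

Binary en-face masks (1 = lumen, 0 = pillar) are extruded into
round(thickness/spacing) layers: the mid-plane reproduces the mask and
each layer at offset d cells is the lumen eroded by a disk of radius d
cells, mimicking circular capillary cross-sections; solid caps close the
stack.  Per-cell P comes from 4× in-plane supersampling (refining the
supersampling changes no cell by more than 1/supersample).  The erosion
radius per layer step equals one cell — the layer count is tied to the
~10 µm anatomic thickness, so resolution controls the fidelity of the
tube-shape taper.

Capillary permutations keep the junction layout fixed and alter only the
mask: *dilated*/*constricted* erode/dilate the pillar phase radially by
2.5 µm; *circularized*/*uniform* replace each connected pillar by a
centroid disc of its own/the mean area; *random* repositions pillar
components (largest first, rejection sampling, ≤10⁴ attempts each)
without overlap, conserving pillar pixels exactly; *open* removes all
pillars.

Synthetic masks are thresholded Gaussian-smoothed white noise: the
threshold is the quantile giving the target en-face density (donor-scale
targets: ~65–75%), and the smoothing scale (default 10 µm) is calibrated
so the mean capillary diameter lands in the donor 17–21 µm range at those
densities.  The small permutation experiment uses a coarser 24 µm texture
instead, so that constricted lumens stay resolvable at its 5 µm cells.
This reproduces the density, diameter scale, and the
irregular anastomotic texture of segmented choriocapillaris, but not the
true pillar shape statistics, spatial anticorrelation with junctions, or
any donor-specific features — results on synthetic anatomies therefore
exercise the machinery and the qualitative density–flow relationships,
not donor-level values.  Junction layouts are Poisson-disc samples at
arteriole/venule densities in the donor range (~4–16 and ~12–30 per mm²)
with a minimum separation (default 60–90 µm).  Junction radii are not
reported for the donor eyes; the generator defaults to 12.5 µm
(arterioles) and 15 µm (venules), venules slightly wider in keeping with
their described morphology.

Anatomic metrics: en-face capillary density is the lumen pixel fraction;
mean capillary diameter is twice the mean Euclidean distance transform on
the lumen medial axis (a measurement definition chosen here; the donor
tables do not specify theirs, so fixture comparisons use this definition
self-consistently).

## Wall stress (`wallstress`)

The strain rate is computed both by central differences of the velocity
(one-sided at array edges) and from the second moment of the
non-equilibrium populations,
S = −Σ e e (n − n^eq) / (2 τ c_s² Σ n); the two agree within 2% on
converged laminar benchmarks.  The total stress adds the isotropic
pressure part −(Σ n c_s²/(1 − P)) δ to the Newtonian deviatoric part
(2τ − 1) c_s² S, and converts to Pa by ρ_phys (dx/dt)².

Wall normals are the normalized gradient of a Gaussian-smoothed
(σ = 1 cell) copy of P, oriented into the solid, defined on boundary
cells and on fluid cells hugging sharp walls.  Voxelized cylinders agree
with the radial direction to a median ~2–3° and anti-aliased spheres to
~1.5°; the error is aliasing-dominated and essentially
radius-independent, because smoothing a radially symmetric field leaves
its gradients exactly radial.

The Cauchy traction T·N splits into the endothelial normal stress
(projection on N) and the endothelial shear stress (tangential
remainder); the decomposition is exact and ESS ⊥ N by construction.  The
stress entering the Cauchy formula is sampled 1 and 2 cells into the
fluid along the inward normal and linearly extrapolated to the wall
plane — for sharp walls that plane lies half a cell beyond the wall-cell
centre (half-way bounce-back); omitting the offset biases channel wall
ESS low by dx/h.  Linear extrapolation is exact for the near-wall linear
shear profiles of laminar flow and recovers the Poiseuille wall shear
G h/2 within 2%.

## Transit tracing (`tracer`)

Corpuscles are advected in the depth-averaged (fluid-volume-weighted)
capillary-plane velocity field by RK4 on bilinear interpolation with an
adaptive step bounded by 0.2 cell per step (halving the step changes exit
times by <0.5%).  Release points sit one cell outside arteriole rims,
apportioned and angled proportionally to the local positive radial flux;
capture occurs on crossing a venule rim.  Particles are flagged stagnant
when slower than 10⁻⁶ of the mean release speed for 100 consecutive
steps or older than 50 domain advective times; stagnant and step-capped
records are excluded from PDFs but always counted
(exited + stagnant + capped = released).

Transit-time PDFs are normalized histograms over exited records (40 bins
by default; comparisons share edges spanning zero to the 99th percentile
of the pooled times).  Kullback-Leibler distances are computed on the
binned masses with a one-observation pseudocount in empty shared bins;
directed and symmetrized variants are available (the symmetrized mean is
the default, as the direction is not specified for the published
distances).  Times are reported in seconds; a normalization by the mean
transit time is available for dimensionless comparisons.

Synthetic-dye lobule maps release a tracer bundle per arteriole and tally
per-cell visitation by source; the dominant source and its mass fraction
(purity) define functional lobules.  Saddle-type stagnation points are
found by Newton refinement of grid speed minima and classified by the
velocity Jacobian; separatrices are traced from each saddle along its
eigenvector directions (unstable forward, stable backward).

## Plane-flow reference (`oracle`)

For the open capillary plane the depth-averaged flow is Hele-Shaw:
ū = −(h²/12μ)∇p with p harmonic away from junctions, so arterioles and
venules act as 2-D point sources/sinks.  Two kernels are provided: the
free-space log superposition, and a periodic spectral solve (FFT Poisson
with the symbol of composed central differences, so the rasterized field
is discretely divergence-free) matching the lattice solver's periodic
lateral boundaries.  Source strengths can be solved from the junction
pressures (a linear system fixing each junction core's pressure, with a
free additive constant and exact flux balance; optionally augmented with
each feeding tube's analytic Poiseuille + orifice series impedance), or
prescribed directly.

For the transit-PDF benchmark the reference field is driven by the
measured per-junction fluxes of the lattice run.  The reduced 2-D model
cannot represent the per-junction series resistance of the ~35 µm feeding
tubes (about a third of the pressure budget at these radii), so sharing
the junction boundary data — standard when validating a 3-D simulation
against a reduced model — isolates the comparison to what the benchmark
actually claims: the in-plane field structure and the transport it
induces.  The pressure-solved oracle remains the default for standalone
use.  The oracle is rasterized at the lattice grid resolution so both
fields carry the same discretization smoothing.

## Summaries (`summaries`, `cli`)

Case summaries report the arithmetic mean, geometric mean and median of
ESS over wall cells, velocity magnitude over capillary-layer fluid cells,
and the arteriole-inlet pressure drop over fluid cells (the averaging
support is a package choice; the donor tables do not state theirs).
Zeros are excluded from geometric means and the exclusion count is kept.
Cross-case averages are area-weighted.  The packaged donor tables (eight
cases: anatomy and hemodynamics) are checksum-pinned CSVs; recomputing
the area-weighted averages from them reproduces the published 1.73 mm/s,
1.69 Pa and 7.4 mmHg (the last printed at one decimal; the recomputed
value is 7.355).

## Problem sizes and runtime choices

The open-plane benchmark runs at 5 µm cells: 800 µm domains (160×160×11
cells, 10 arterioles / 20 venules) for the scripted validation and
720 µm domains for the three-seed test, with 3000 corpuscles per field —
pooled over the ~10 segments as in the published PDF methodology.  The
permutation experiment uses a 360 µm synthetic case with 2 arterioles /
4 venules.  These desk-scale sizes preserve the governing dimensionless
ratios (gap/junction radius, junction spacing/domain) while keeping a
full validation run in minutes on one CPU core; they are not the
donor-tissue sizes (2.5 mm, ~80–150 junctions), and donor-level absolute
values are out of reach without the unpublished donor geometries.

## Known limitations

* Weak compressibility: the 8.6 mmHg drive produces ~15% lattice density
  variation; velocity fields are accurate to ~Ma² but the prescribed
  volumetric fluxes differ between inlet and outlet by the density ratio
  (hence mass-flux-based junction fluxes).
* The capillary gap resolves to 2 cells at 5 µm spacing: the in-gap
  profile is under-resolved, which is absorbed by flux matching in the
  oracle comparison but limits absolute wall-ESS accuracy on the
  capillary walls at that spacing.
* No pulsatility, rigid walls, Newtonian rheology, flat geometry —
  deliberate simplifications of the underlying model.
* The tracer is purely advective (no diffusion, no red-cell mechanics);
  dye maps are pathline bundles, not concentration fields.
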