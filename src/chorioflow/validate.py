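"""End-to-end validation of the lattice solver against the plane-flow oracle.

Reproduces the open-plane benchmark: a quasi-random arteriole/venule layout
on an empty capillary plane is solved twice — by the volumetric lattice
Boltzmann method in 3-D (with capping layers and feeding tubes) and by the
depth-averaged Hele-Shaw reference sharing the same junction boundary
fluxes — and the two arteriole-to-venule transit-time PDFs are compared by
Pearson correlation on shared bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (BoundaryConfig, ConvergenceSpec, junction_fluxes,
                     pressure_init_guess, run_to_steady)
from .geometry import (BinaryCapillaryMask, JunctionMap, PermutationSpec,
                       build_occupancy_from_mask, capillary_density,
                       generate_quasirandom_layout, generate_synthetic_mask,
                       mount_junctions, permute_capillaries)
from .oracle import layout_from_fluxes, solve_plane_potential
from .tracer import (TransitPDF, pdf_pearson, planar_field_from_macro,
                     shared_transit_pdfs, trace_particles)
from .units import FluidProperties, map_units
from .wallstress import (estimate_wall_normals, strain_rate_moment,
                         total_stress, wall_stress)

__all__ = ["OpenPlaneComparison", "open_plane_comparison",
           "permutation_response"]


@dataclass
class OpenPlaneComparison:
    """Result of one lattice-vs-oracle open-plane benchmark."""

    pearson_r: float
    pdf_lattice: TransitPDF
    pdf_oracle: TransitPDF
    n_particles: int
    n_arterioles: int
    n_venules: int
    steps: int
    converged: bool
    mean_speed_mm_s: float
    jmap: JunctionMap


def open_plane_comparison(seed: int,
                          side_um: float = 800.0,
                          spacing_um: float = 5.0,
                          n_arterioles: int = 10,
                          n_venules: int = 20,
                          min_sep_um: float = 90.0,
                          thickness_um: float = 10.0,
                          tube_depth_um: float = 35.0,
                          n_particles: int = 3000,
                          tau: float = 1.0,
                          tol: float = 1e-6,
                          max_steps: int = 30_000,
                          bc: BoundaryConfig | None = None,
                          fluid: FluidProperties | None = None,
                          progress: bool = False) -> OpenPlaneComparison:
    """Run the full open-plane benchmark for one layout seed.

    The layout (about ``n_arterioles`` vascular segments) is generated
    quasi-randomly; the lattice solver runs to steady state under the
    physiologic pressure pair; at least ``n_particles`` corpuscles are
    traced through both the simulated and the reference field with
    seed-decoupled release sampling.
    """
    bc = bc or BoundaryConfig()
    fluid = fluid or FluidProperties()
    area_mm2 = (side_um / 1000.0) ** 2
    jmap = generate_quasirandom_layout(
        area_mm2, n_arterioles / area_mm2, n_venules / area_mm2,
        min_sep_um=min_sep_um, seed=seed)
    n_px = int(round(side_um / 4.0))
    mask = BinaryCapillaryMask(np.ones((n_px, n_px), np.uint8), 4.0)
    grid = build_occupancy_from_mask(mask, thickness_um=thickness_um,
                                     spacing_um=spacing_um)
    grid = mount_junctions(grid, jmap, tube_depth_um=tube_depth_um)

    units = map_units(fluid, dx=spacing_um * 1e-6, tau=tau)
    rho0 = pressure_init_guess(grid, bc, units)
    res = run_to_steady(grid, bc, fluid,
                        ConvergenceSpec(tol=tol, check_every=200,
                                        max_steps=max_steps),
                        tau=tau, rho_init=rho0, progress=progress)

    field = planar_field_from_macro(res.macro, grid)
    fluxes = junction_fluxes(res, grid)
    layout = layout_from_fluxes(jmap, fluxes,
                                domain_um=(side_um, side_um),
                                gap_um=thickness_um)
    oracle_field = solve_plane_potential(layout, field.shape,
                                         kernel="periodic", fluid=fluid)

    rec_lat = trace_particles(field, jmap, n_particles=n_particles,
                              seed=seed * 7919 + 1)
    rec_ora = trace_particles(oracle_field, jmap, n_particles=n_particles,
                              seed=seed * 7919 + 2)
    pdf_lat, pdf_ora = shared_transit_pdfs(rec_lat, rec_ora)
    r = pdf_pearson(pdf_lat, pdf_ora)
    return OpenPlaneComparison(
        pearson_r=r, pdf_lattice=pdf_lat, pdf_oracle=pdf_ora,
        n_particles=n_particles, n_arterioles=len(jmap.arterioles),
        n_venules=len(jmap.venules), steps=res.steps,
        converged=res.converged,
        mean_speed_mm_s=float(
            res.macro.speed[:, :, grid.layer_index].mean() * 1e3),
        jmap=jmap)


def permutation_response(seed: int = 0,
                         modes: tuple[str, ...] = ("constricted", "original",
                                                   "open"),
                         side_um: float = 360.0,
                         spacing_um: float = 5.0,
                         pixel_size_um: float = 2.0,
                         target_density: float = 70.0,
                         tau: float = 1.0,
                         tol: float = 1e-5,
                         max_steps: int = 12_000):
    """Capillary-permutation experiment on one synthetic case.

    A synthetic anastomotic mask is permuted (arteriole/venule layout held
    fixed), each anatomy is solved to steady state, and the en-face
    capillary density is related to the mean capillary-plane velocity and
    the mean wall ESS.  Returns a list of
    ``(mode, density_pct, mean_velocity_mm_s, mean_ess_pa)`` rows suitable
    for :func:`chorioflow.summaries.density_response_curve`.
    """
    bc = BoundaryConfig()
    fluid = FluidProperties()
    mask0 = generate_synthetic_mask(side_um, side_um, target_density,
                                    pillar_scale_um=24.0,
                                    pixel_size_um=pixel_size_um, seed=seed)
    area_mm2 = (side_um / 1000.0) ** 2
    jmap = generate_quasirandom_layout(area_mm2, 2 / area_mm2, 4 / area_mm2,
                                       min_sep_um=90.0, seed=seed + 1)
    rows = []
    for mode in modes:
        mask = permute_capillaries(mask0, PermutationSpec(mode=mode,
                                                          seed=seed + 2))
        grid = build_occupancy_from_mask(mask, thickness_um=10.0,
                                         spacing_um=spacing_um)
        grid = mount_junctions(grid, jmap, tube_depth_um=35.0)
        units = map_units(fluid, dx=spacing_um * 1e-6, tau=tau)
        res = run_to_steady(grid, bc, fluid,
                            ConvergenceSpec(tol=tol, check_every=200,
                                            max_steps=max_steps),
                            tau=tau,
                            rho_init=pressure_init_guess(grid, bc, units))
        zsl = grid.capillary_layers()
        fluid_cells = grid.P[:, :, zsl] < 1.0
        mean_v = float(res.macro.speed[:, :, zsl][fluid_cells].mean() * 1e3)
        n = res.populations
        S = strain_rate_moment(n, tau, grid.P)
        T = total_stress(n, S, grid.P, tau, units=units)
        normals, defined = estimate_wall_normals(grid.P)
        # restrict the ESS statistic to the capillary layers
        zmask = np.zeros_like(defined)
        zmask[:, :, zsl] = True
        wall = wall_stress(T, normals, defined & zmask, grid.P)
        ess = wall.ess_magnitude
        mean_ess = float(ess[np.isfinite(ess)].mean())
        rows.append((mode, capillary_density(mask), mean_v, mean_ess))
    return rows
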