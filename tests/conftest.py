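"""Shared fixtures: converged channel benchmarks and small geometries."""

from __future__ import annotations

import numpy as np
import pytest

from chorioflow.engine import BoundaryConfig, ConvergenceSpec, run_to_steady
from chorioflow.geometry import BinaryCapillaryMask, OccupancyGrid
from chorioflow.units import FluidProperties, map_units

TAU = 1.0
CS2 = 1.0 / 3.0


def channel_grid(h_cells: int, lateral: int = 4,
                 spacing_um: float = 2.0) -> OccupancyGrid:
    """Plane channel: solid caps in z, periodic x-y, h_cells fluid cells."""
    P = np.zeros((lateral, lateral, h_cells + 2))
    P[:, :, 0] = 1.0
    P[:, :, -1] = 1.0
    return OccupancyGrid(P=P, spacing_um=spacing_um,
                         layer_index=(h_cells + 2) // 2)


def poiseuille_setup(h_cells: int, u_max_lat: float = 0.05):
    """Body-force-driven Poiseuille problem with its analytic solution.

    Returns (grid, bc, fluid, g_lat) where g_lat is the lattice force
    density; the physical acceleration passed to the solver is -g (the
    forcing convention drives flow along -a).
    """
    grid = channel_grid(h_cells)
    nu_lat = CS2 * (TAU - 0.5)
    g_lat = 8.0 * nu_lat * u_max_lat / h_cells**2
    fluid = FluidProperties()
    units = map_units(fluid, dx=grid.spacing_um * 1e-6, tau=TAU)
    a_phys = -g_lat * units.dx / units.dt**2
    bc = BoundaryConfig(body_acceleration=(a_phys, 0.0, 0.0))
    return grid, bc, fluid, g_lat


def run_poiseuille(h_cells: int):
    grid, bc, fluid, g_lat = poiseuille_setup(h_cells)
    res = run_to_steady(grid, bc, fluid,
                        ConvergenceSpec(tol=1e-10, check_every=200,
                                        max_steps=60_000), tau=TAU)
    return grid, res, g_lat


@pytest.fixture(scope="session")
def poiseuille32():
    """Converged 32-cell plane Poiseuille benchmark (shared, ~1 min)."""
    return run_poiseuille(32)


@pytest.fixture(scope="session")
def poiseuille16():
    return run_poiseuille(16)


@pytest.fixture()
def strip_mask():
    """Straight lumen strip of width 40 px in a 64x96 pillar field."""
    px = np.zeros((64, 96), np.uint8)
    px[12:52, :] = 1
    return BinaryCapillaryMask(px, pixel_size_um=1.0)


@pytest.fixture()
def pillar_mask():
    """Open plane with a single square pillar."""
    px = np.ones((64, 64), np.uint8)
    px[24:40, 24:40] = 0
    return BinaryCapillaryMask(px, pixel_size_um=2.0)
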