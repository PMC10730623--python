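"""Volumetric lattice Boltzmann solver for pressure-driven perfusion.

The solver evolves per-cell particle populations ``n_i`` on an
:class:`~chorioflow.geometry.OccupancyGrid` by BGK collision and volumetric
streaming with partial bounce-back in boundary cells (0 < P < 1).  Blood is
driven by prescribed densities (pressures) on the arteriole/venule tube end
faces; the lateral domain boundaries are periodic and all walls are rigid.

Lattice populations relate to the node-based distribution by
``n_i = (1 - P) f_i``, so in fluid cells (P = 0) the scheme reduces to the
standard lattice Boltzmann method with half-way bounce-back at sharp walls.
Macroscopic fields follow from the population moments:
``rho = sum_i n_i / (1 - P)``, ``u = sum_i e_i n_i / sum_i n_i``, and
``p - p0 = cs2 (rho - rho0)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import OccupancyGrid
from .lattice import D3Q19, LatticeModel
from .units import MMHG_TO_PA, FluidProperties, UnitSystem, map_units

__all__ = [
    "BoundaryConfig",
    "ConvergenceSpec",
    "MacroFields",
    "SimulationResult",
    "equilibrium",
    "forcing",
    "collide",
    "stream",
    "macroscopic",
    "apply_pressure_boundaries",
    "initialize_populations",
    "run_to_steady",
    "junction_fluxes",
]


@dataclass(frozen=True)
class BoundaryConfig:
    """Driving pressures (mmHg) and optional body acceleration (m/s^2).

    Defaults reproduce the physiologic calibration used for the donor
    simulations: 44.2 mmHg at arteriole inlets, 35.6 mmHg at venule
    outlets.  The lateral boundaries are always periodic.
    """

    p_art_mmhg: float = 44.2
    p_ven_mmhg: float = 35.6
    body_acceleration: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.p_art_mmhg < self.p_ven_mmhg:
            raise ValueError("arteriole pressure must be >= venule pressure")

    @property
    def delta_p_pa(self) -> float:
        return (self.p_art_mmhg - self.p_ven_mmhg) * MMHG_TO_PA


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stopping rule for the steady-state driver.

    The run stops when the relative L2 change of the velocity field over
    ``check_every`` steps drops below ``tol``.
    """

    tol: float = 1e-6
    check_every: int = 100
    max_steps: int = 200_000


@dataclass
class MacroFields:
    """Macroscopic fields, in lattice units plus SI conversions."""

    rho: np.ndarray          # lattice density, (nx, ny, nz)
    u_lat: np.ndarray        # lattice velocity, (3, nx, ny, nz)
    P: np.ndarray            # solid volume fraction
    units: UnitSystem
    p0_pa: float             # physical pressure anchored at rho = 1
    layer_index: int = 0
    fluid_mask: np.ndarray | None = None

    @property
    def velocity(self) -> np.ndarray:
        """Velocity in m/s, (3, nx, ny, nz)."""
        return self.u_lat * self.units.velocity_scale

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.velocity**2).sum(axis=0))

    @property
    def pressure(self) -> np.ndarray:
        """Absolute pressure in Pa (p0 anchored at the venule outlets)."""
        return self.p0_pa + (self.units.cs2 * (self.rho - 1.0)
                             * self.units.pressure_scale)


@dataclass
class SimulationResult:
    macro: MacroFields
    populations: np.ndarray
    steps: int
    converged: bool
    residual_history: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations (also exposed for testing)
# ---------------------------------------------------------------------------

def equilibrium(N: np.ndarray, u: np.ndarray,
                lattice: LatticeModel | None = None) -> np.ndarray:
    """Incompressible-flow equilibria from the zeroth moment and velocity.

    ``N`` has any shape S, ``u`` shape (3,) + S (or (3,) for scalars);
    returns shape (b,) + S.  Raises if any |u| >= c_s.
    """
    lattice = lattice or D3Q19()
    N = np.asarray(N, dtype=float)
    u = np.asarray(u, dtype=float)
    if u.shape == (3,) and N.ndim == 0:
        u = u.reshape(3, 1)
        N = N.reshape(1)
        squeeze = True
    else:
        squeeze = False
    if np.any((u**2).sum(axis=0) >= lattice.cs2):
        raise ValueError("velocity out of lattice range (|u| >= c_s)")
    cs2 = lattice.cs2
    eu = np.tensordot(lattice.e.astype(float), u, axes=(1, 0))  # (b,) + S
    usq = (u**2).sum(axis=0)
    w = lattice.w.reshape((-1,) + (1,) * N.ndim)
    neq = N * w * (1.0 + eu / cs2 + eu**2 / (2 * cs2**2) - usq / (2 * cs2))
    return neq[:, 0] if squeeze else neq


def forcing(a: np.ndarray, N: np.ndarray,
            lattice: LatticeModel | None = None) -> np.ndarray:
    """Per-direction forcing F_i = -w_i N (e_i . a) / cs2 (delta t = 1).

    The direction sums vanish for the zeroth moment and equal ``-N a`` for
    the first moment, so a positive flow along +g is driven by ``a = -g``.
    """
    lattice = lattice or D3Q19()
    a = np.asarray(a, dtype=float)
    N = np.asarray(N, dtype=float)
    ea = np.tensordot(lattice.e.astype(float), a, axes=(1, 0))
    w = lattice.w.reshape((-1,) + (1,) * N.ndim)
    return -w * N * ea / lattice.cs2


def collide(n: np.ndarray, tau: float,
            a: tuple[float, float, float] = (0.0, 0.0, 0.0),
            P: np.ndarray | None = None,
            lattice: LatticeModel | None = None) -> np.ndarray:
    """BGK collision n' = n - (n - n_eq)/tau + F on a (b, nx, ny, nz) field."""
    if tau <= 0.5:
        raise ValueError("tau must exceed 1/2")
    lattice = lattice or D3Q19()
    n = np.ascontiguousarray(n, dtype=np.float64)
    if P is None:
        P = np.zeros(n.shape[1:], dtype=np.float64)
    n_post = np.empty_like(n)
    _kernels.collide_kernel(n, n_post, np.ascontiguousarray(P, np.float64),
                            lattice.e, lattice.w, lattice.opp, lattice.cs2,
                            float(tau), np.asarray(a, dtype=np.float64))
    return n_post


def stream(n_post: np.ndarray, P: np.ndarray,
           lattice: LatticeModel | None = None) -> np.ndarray:
    """Volumetric streaming of post-collision populations (gather form)."""
    lattice = lattice or D3Q19()
    n_post = np.ascontiguousarray(n_post, dtype=np.float64)
    n_new = np.empty_like(n_post)
    _kernels.stream_kernel(n_post, n_new,
                           np.ascontiguousarray(P, np.float64),
                           lattice.e, lattice.opp)
    return n_new


def macroscopic(n: np.ndarray, P: np.ndarray,
                lattice: LatticeModel | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Density and velocity from population moments.

    Returns ``(rho, u)`` with ``rho = sum n / (1 - P)`` and
    ``u = sum e n / sum n``; cells with no population (solid, or empty) are
    masked to zero velocity and rho = 0.
    """
    lattice = lattice or D3Q19()
    N = n.sum(axis=0)
    valid = (P < 1.0) & (N > 0)
    rho = np.zeros_like(N)
    rho[valid] = N[valid] / (1.0 - P[valid])
    u = np.tensordot(lattice.e.astype(float).T, n, axes=(1, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(valid, u / N, 0.0)
    return rho, u


def initialize_populations(grid: OccupancyGrid,
                           rho_init: np.ndarray | float = 1.0,
                           lattice: LatticeModel | None = None) -> np.ndarray:
    """Quiescent populations n_i = (1 - P) rho w_i."""
    lattice = lattice or D3Q19()
    vol = (1.0 - grid.P) * np.asarray(rho_init, dtype=float)
    return lattice.w.reshape(-1, 1, 1, 1) * vol[None]


# ---------------------------------------------------------------------------
# pressure boundaries
# ---------------------------------------------------------------------------

def _face_arrays(cells_by_id: dict[int, np.ndarray]) -> np.ndarray:
    if not cells_by_id:
        return np.zeros((3, 0), dtype=np.int64)
    return np.concatenate([np.asarray(c) for c in cells_by_id.values()],
                          axis=1)


def apply_pressure_boundaries(n: np.ndarray, grid: OccupancyGrid,
                              bc: BoundaryConfig, units: UnitSystem,
                              lattice: LatticeModel | None = None,
                              _warn_state: dict | None = None) -> np.ndarray:
    """Impose prescribed densities on the junction tube end faces (in place).

    Non-equilibrium extrapolation: each face cell is rebuilt as the
    equilibrium at the target density with the adjacent interior cell's
    velocity, plus that interior cell's non-equilibrium part.  The venule
    outlets anchor the lattice reference density (rho = 1); arteriole
    inlets carry rho = 1 + dp_lattice / cs2.
    """
    lattice = lattice or D3Q19()
    inlets = _face_arrays(grid.inlet_cells)
    outlets = _face_arrays(grid.outlet_cells)
    if inlets.shape[1] == 0 or outlets.shape[1] == 0:
        raise ValueError("pressure boundaries need >= 1 inlet and 1 outlet")
    dp_lat = units.pressure_to_lattice(bc.delta_p_pa)
    rho_in = 1.0 + dp_lat / units.cs2
    nz = n.shape[3]
    for cells, rho_target in ((inlets, rho_in), (outlets, 1.0)):
        ix, iy, iz = cells
        # interior neighbour along the tube axis (faces sit on a z extreme)
        fx, fy = ix, iy
        fz = np.where(iz == 0, iz + 1, iz - 1)
        nf = n[:, fx, fy, fz]                # (b, k)
        Nf = nf.sum(axis=0)
        Nf = np.where(Nf > 0, Nf, 1.0)
        uf = np.tensordot(lattice.e.astype(float).T, nf, axes=(1, 0)) / Nf
        speed = np.sqrt((uf**2).sum(axis=0))
        if (_warn_state is not None and not _warn_state.get("warned")
                and speed.max() > 0.1 * np.sqrt(units.cs2)):
            _warn_state["warned"] = True
            warnings.warn("compressibility error: local Mach > 0.1 at "
                          "pressure faces", stacklevel=2)
        uf = np.clip(uf, -0.3, 0.3)
        neq_f = equilibrium(Nf, uf, lattice)
        neq_t = equilibrium(np.full_like(Nf, rho_target), uf, lattice)
        n[:, ix, iy, iz] = neq_t + (nf - neq_f)
    return n


# ---------------------------------------------------------------------------
# steady-state driver
# ---------------------------------------------------------------------------

def pressure_init_guess(grid: OccupancyGrid, bc: BoundaryConfig,
                        units: UnitSystem,
                        lattice: LatticeModel | None = None) -> np.ndarray:
    """Smooth initial density field from a 2-D Laplace interpolation.

    Solves the discrete Laplace equation on the lateral plane (periodic
    wrap) with Dirichlet values at the junction discs — the arteriole /
    venule target densities — and broadcasts the result over z.  This is
    only an initial guess to shorten the acoustic transient; the steady
    state is still defined by the lattice dynamics and the convergence
    criterion.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    lattice = lattice or D3Q19()
    nx, ny, _ = grid.P.shape
    dp_lat = units.pressure_to_lattice(bc.delta_p_pa)
    rho_in = 1.0 + dp_lat / units.cs2
    fixed = np.full((nx, ny), np.nan)
    for cells_by_id, rho_t in ((grid.inlet_cells, rho_in),
                               (grid.outlet_cells, 1.0)):
        for cells in cells_by_id.values():
            ix, iy, _ = np.asarray(cells)
            fixed[ix, iy] = rho_t
    if np.isnan(fixed).all():
        return np.ones((nx, ny, 1))
    idx = np.arange(nx * ny).reshape(nx, ny)
    A = lil_matrix((nx * ny, nx * ny))
    rhs = np.zeros(nx * ny)
    free = np.isnan(fixed)
    for x in range(nx):
        for y in range(ny):
            k = idx[x, y]
            if not free[x, y]:
                A[k, k] = 1.0
                rhs[k] = fixed[x, y]
                continue
            A[k, k] = -4.0
            for xn, yn in (((x + 1) % nx, y), ((x - 1) % nx, y),
                           (x, (y + 1) % ny), (x, (y - 1) % ny)):
                A[k, idx[xn, yn]] = 1.0
    rho2d = spsolve(A.tocsr(), rhs).reshape(nx, ny)
    return rho2d[:, :, None]


def run_to_steady(grid: OccupancyGrid,
                  bc: BoundaryConfig | None = None,
                  fluid: FluidProperties | None = None,
                  conv: ConvergenceSpec | None = None,
                  tau: float = 0.8,
                  lattice: LatticeModel | None = None,
                  rho_init: np.ndarray | float = 1.0,
                  progress: bool = False) -> SimulationResult:
    """Iterate collide -> stream -> pressure boundaries to steady state.

    Convergence is declared when the relative L2 change of the velocity
    field between checks ``conv.check_every`` steps apart falls below
    ``conv.tol``.  Raises on divergence (NaN populations), reporting the
    last stable iteration.
    """
    bc = bc or BoundaryConfig()
    fluid = fluid or FluidProperties()
    conv = conv or ConvergenceSpec()
    lattice = lattice or D3Q19()
    units = map_units(fluid, dx=grid.spacing_um * 1e-6, tau=tau,
                      cs2=lattice.cs2)
    P = np.ascontiguousarray(grid.P, dtype=np.float64)
    has_faces = bool(grid.inlet_cells) and bool(grid.outlet_cells)
    a_phys = np.asarray(bc.body_acceleration, dtype=float)
    a_lat = np.array([units.acceleration_to_lattice(ai) for ai in a_phys])
    n = initialize_populations(grid, rho_init, lattice)
    n_post = np.empty_like(n)
    warn_state: dict = {}
    u_prev = None
    history: list[tuple[int, float]] = []
    converged = False
    step = 0
    while step < conv.max_steps:
        _kernels.collide_kernel(n, n_post, P, lattice.e, lattice.w,
                                lattice.opp, lattice.cs2, float(tau), a_lat)
        _kernels.stream_kernel(n_post, n, P, lattice.e, lattice.opp)
        if has_faces:
            apply_pressure_boundaries(n, grid, bc, units, lattice,
                                      _warn_state=warn_state)
        step += 1
        if step % conv.check_every == 0:
            _, u = macroscopic(n, P, lattice)
            if not np.isfinite(u).all():
                raise RuntimeError(
                    f"divergence detected at step {step}; last stable "
                    f"iteration {step - conv.check_every}")
            if u_prev is not None:
                num = np.sqrt(((u - u_prev)**2).sum())
                den = np.sqrt((u**2).sum())
                res = num / den if den > 0 else 0.0
                history.append((step, float(res)))
                if progress:
                    print(f"step {step}: residual {res:.3e}")
                if res < conv.tol:
                    converged = True
                    break
            u_prev = u

    rho, u = macroscopic(n, P, lattice)
    macro = MacroFields(rho=rho, u_lat=u, P=P, units=units,
                        p0_pa=bc.p_ven_mmhg * MMHG_TO_PA,
                        layer_index=grid.layer_index,
                        fluid_mask=(P < 1.0) & (n.sum(axis=0) > 0))
    return SimulationResult(macro=macro, populations=n, steps=step,
                            converged=converged, residual_history=history)


def junction_fluxes(result: SimulationResult, grid: OccupancyGrid
                    ) -> dict[int, float]:
    """Volumetric flux (m^3/s) through each junction tube cross-section.

    Positive values flow into the domain (arterioles), negative out
    (venules).  The mass flux (rho u_z per cell, rim columns weighted by
    their open fraction) is integrated over the tube cross-section one
    layer below the end face and normalized by the reference density, so
    inlet and outlet fluxes balance exactly at steady state even though
    the prescribed densities differ slightly between the faces.
    """
    if grid.junctions is None:
        raise ValueError("grid carries no junction map")
    u = result.macro.velocity
    dx = result.macro.units.dx
    h = grid.spacing_um
    nx, ny, nz = grid.P.shape
    zm = nz - 2
    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    open_frac = 1.0 - grid.P[:, :, zm]
    uz_rho = u[2, :, :, zm] * result.macro.rho[:, :, zm]
    fluxes: dict[int, float] = {}
    for j in grid.junctions.junctions:
        m = (np.hypot(X - j.center_um[0], Y - j.center_um[1])
             <= j.radius_um + h) & (open_frac > 0)
        fluxes[j.id] = float(-(uz_rho[m] * open_frac[m]).sum() * dx**2)
    return fluxes
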