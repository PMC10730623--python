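"""Independent reference flows for validating the lattice solver.

Two families of closed-form / spectral solutions are provided:

* **Hele-Shaw source/sink flow** for the open capillary plane.  Arterioles
  and venules act as point sources and sinks of the depth-averaged 2-D
  flow; their strengths are solved from the prescribed junction pressures
  through a linear map (log-kernel superposition in free space, or an FFT
  Poisson solve honouring the periodic lateral boundaries used by the
  lattice solver).
* **Plane Poiseuille flow**, the standard channel benchmark with profile
  ``u(y) = G y (h - y) / (2 mu)``.

The oracle shares no code with the lattice solver; agreement of the two on
the same layout is the primary validation of the simulated perfusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import JunctionMap
from .units import MMHG_TO_PA, FluidProperties

__all__ = [
    "SourceSinkLayout",
    "AnalyticChannel",
    "layout_from_junctions",
    "solve_plane_potential",
    "analytic_poiseuille",
    "divergence",
]


@dataclass
class SourceSinkLayout:
    """Point sources (arterioles, +) and sinks (venules, -) in a gap.

    ``strengths`` are volumetric fluxes in m^3/s and sum to zero;
    ``core_radius_um`` regularizes each singularity at the junction radius.
    """

    positions_um: np.ndarray     # (N, 2)
    strengths_m3s: np.ndarray    # (N,)
    domain_um: tuple[float, float]
    gap_um: float
    core_radius_um: np.ndarray   # (N,)

    def __post_init__(self) -> None:
        self.positions_um = np.atleast_2d(np.asarray(self.positions_um,
                                                     dtype=float))
        self.strengths_m3s = np.asarray(self.strengths_m3s, dtype=float)
        self.core_radius_um = np.broadcast_to(
            np.asarray(self.core_radius_um, dtype=float),
            (self.positions_um.shape[0],)).copy()
        total = self.strengths_m3s.sum()
        scale = np.abs(self.strengths_m3s).sum()
        if scale > 0 and abs(total) > 1e-9 * scale:
            # Project to exact flux balance; a large imbalance is a user error
            # upstream, a small one is round-off.
            import warnings
            if abs(total) > 1e-3 * scale:
                warnings.warn("unbalanced layout projected to zero net flux",
                              stacklevel=2)
            self.strengths_m3s = self.strengths_m3s - total / len(
                self.strengths_m3s)

    @property
    def total_source_flux(self) -> float:
        """Sum of positive strengths, m^3/s."""
        return float(self.strengths_m3s[self.strengths_m3s > 0].sum())


@dataclass(frozen=True)
class AnalyticChannel:
    """Plane channel of height h driven by pressure gradient G."""

    height_m: float
    pressure_gradient: float  # Pa/m, along the flow
    dynamic_viscosity: float  # Pa s

    def __post_init__(self) -> None:
        if self.height_m <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("height and viscosity must be positive")


# ---------------------------------------------------------------------------
# Hele-Shaw source/sink oracle
# ---------------------------------------------------------------------------

def _depth_avg_velocity_free(layout: SourceSinkLayout,
                             points_um: np.ndarray) -> np.ndarray:
    """Free-space superposition: u = sum q_k (x - x_k) / (2 pi h r^2).

    Depth-averaged velocity in m/s at the given (K, 2) points (um); each
    kernel is regularized inside its core radius (solid-body ramp).
    """
    pts = np.atleast_2d(points_um) * 1e-6
    pos = layout.positions_um * 1e-6
    h = layout.gap_um * 1e-6
    core = layout.core_radius_um * 1e-6
    u = np.zeros_like(pts)
    for k in range(pos.shape[0]):
        d = pts - pos[k]
        r2 = (d**2).sum(axis=1)
        r2 = np.maximum(r2, core[k]**2)
        u += layout.strengths_m3s[k] / (2 * np.pi * h) * d / r2[:, None]
    return u


def _fft_poisson(rhs: np.ndarray, dx_m: float) -> np.ndarray:
    """Periodic solution of lap(p) = rhs (zero-mean), cell spacing dx."""
    nx, ny = rhs.shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx_m)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=dx_m)
    # Symbol of the composed central first differences, so that the
    # central-difference gradient of p is discretely divergence-free off
    # the sources.  Nyquist modes (sin = 0 at nonzero k) are projected out.
    sx = np.sin(kx * dx_m) / dx_m
    sy = np.sin(ky * dx_m) / dx_m
    lam = -(sx**2)[:, None] - (sy**2)[None, :]
    # sin(pi) is ~1e-16, not 0: catch the Nyquist modes by magnitude or
    # their round-off amplifies into a physical-signal-destroying
    # checkerboard.
    singular = np.abs(lam) < 1e-10 * np.abs(lam).max()
    lam[singular] = 1.0
    rhat = np.fft.fft2(rhs - rhs.mean())
    phat = rhat / lam
    phat[singular] = 0.0
    return np.real(np.fft.ifft2(phat))


def _deposit_discs(jmap: JunctionMap, shape: tuple[int, int],
                   spacing_um: float) -> list[np.ndarray]:
    """Unit-flux source density (1/m^2 scaled) per junction, disc-smoothed."""
    nx, ny = shape
    xs = (np.arange(nx) + 0.5) * spacing_um
    ys = (np.arange(ny) + 0.5) * spacing_um
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    deposits = []
    for j in jmap.junctions:
        m = ((X - j.center_um[0])**2 + (Y - j.center_um[1])**2
             <= j.radius_um**2).astype(float)
        if m.sum() == 0:  # radius below the grid: single nearest cell
            ix = int(j.center_um[0] / spacing_um)
            iy = int(j.center_um[1] / spacing_um)
            m[ix % nx, iy % ny] = 1.0
        deposits.append(m / (m.sum() * (spacing_um * 1e-6)**2))
    return deposits


def layout_from_fluxes(jmap: JunctionMap, fluxes_m3s: dict[int, float],
                       domain_um: tuple[float, float],
                       gap_um: float = 10.0) -> SourceSinkLayout:
    """Layout whose strengths are prescribed per-junction fluxes.

    Used to drive the reference solution with the same junction boundary
    fluxes as a lattice run: the depth-averaged Hele-Shaw model cannot
    represent the series resistance of the feeding tubes, so sharing the
    boundary data isolates the comparison to the in-plane field structure
    and transport.  Strengths are balanced to zero net flux.
    """
    juncs = jmap.junctions
    pos = np.array([j.center_um for j in juncs])
    core = np.array([j.radius_um for j in juncs])
    q = np.array([fluxes_m3s[j.id] for j in juncs], dtype=float)
    q = q - q.sum() / len(q)
    return SourceSinkLayout(positions_um=pos, strengths_m3s=q,
                            domain_um=domain_um, gap_um=gap_um,
                            core_radius_um=core)


def layout_from_junctions(jmap: JunctionMap,
                          domain_um: tuple[float, float],
                          gap_um: float = 10.0,
                          p_art_mmhg: float = 44.2,
                          p_ven_mmhg: float = 35.6,
                          fluid: FluidProperties | None = None,
                          kernel: str = "periodic",
                          grid_shape: tuple[int, int] | None = None,
                          spacing_um: float | None = None,
                          tube_length_um: float = 0.0,
                          ) -> SourceSinkLayout:
    """Solve junction strengths from the prescribed pressures.

    In the Hele-Shaw gap the depth-averaged velocity is
    ``u = -(h^2 / 12 mu) grad p`` with harmonic pressure away from the
    junctions, so the junction strengths follow from a linear system that
    fixes the pressure at each junction core to the arteriole/venule value
    (with an additive constant absorbing the free reference level).

    ``kernel='free'`` uses the log superposition; ``kernel='periodic'``
    builds the response matrix from spectral Poisson solves on a grid
    matching the lattice solver's periodic lateral boundaries.  A nonzero
    ``tube_length_um`` adds each junction's feeding-tube series impedance
    (Poiseuille tube law plus a Sampson orifice end correction) between
    its prescribed pressure and the plane.
    """
    fluid = fluid or FluidProperties()
    mu = fluid.dynamic_viscosity
    h = gap_um * 1e-6
    juncs = jmap.junctions
    N = len(juncs)
    pos = np.array([j.center_um for j in juncs])
    core = np.array([j.radius_um for j in juncs])
    p_t = np.array([(p_art_mmhg if j.kind == "arteriole" else p_ven_mmhg)
                    * MMHG_TO_PA for j in juncs])
    if tube_length_um > 0:
        a_m = core * 1e-6
        R_series = (8 * mu * tube_length_um * 1e-6 / (np.pi * a_m**4)
                    + 3 * mu / a_m**3)
    else:
        R_series = np.zeros(N)

    if kernel == "free":
        # p(x_j) = sum_k c_k ln r_jk + C with c_k = -12 mu q_k / (2 pi h^3)
        r = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1]) * 1e-6
        np.fill_diagonal(r, core * 1e-6)
        kfac = -12 * mu / (2 * np.pi * h**3)   # pressure per unit strength
        A = np.zeros((N + 1, N + 1))
        A[:N, :N] = np.log(r) * kfac + np.diag(R_series)
        A[:N, N] = 1.0
        A[N, :N] = np.abs(A[:N, :N]).max()
        rhs = np.concatenate([p_t, [0.0]])
        sol = np.linalg.solve(A, rhs)
        q = sol[:N]
    elif kernel == "periodic":
        if spacing_um is None:
            spacing_um = max(domain_um) / 192 if grid_shape is None \
                else domain_um[0] / grid_shape[0]
        nx = grid_shape[0] if grid_shape else int(round(domain_um[0]
                                                        / spacing_um))
        ny = grid_shape[1] if grid_shape else int(round(domain_um[1]
                                                        / spacing_um))
        dx_m = spacing_um * 1e-6
        deposits = _deposit_discs(jmap, (nx, ny), spacing_um)
        # Unit-flux pressure responses: lap p = -(12 mu / h^3) * sigma
        basis = [_fft_poisson(-12 * mu / h**3 * d, dx_m) for d in deposits]
        xs = (np.arange(nx) + 0.5) * spacing_um
        ys = (np.arange(ny) + 0.5) * spacing_um
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        M = np.zeros((N, N))
        for jj, j in enumerate(juncs):
            m = ((X - j.center_um[0])**2 + (Y - j.center_um[1])**2
                 <= j.radius_um**2)
            if not m.any():
                m = deposits[jj] > 0
            for kk in range(N):
                M[jj, kk] = basis[kk][m].mean()
        # Scale the flux-balance row to the magnitude of the pressure rows
        # so the square system stays well conditioned.
        M = M + np.diag(R_series)
        s = np.abs(M).max()
        A = np.zeros((N + 1, N + 1))
        A[:N, :N] = M
        A[:N, N] = 1.0
        A[N, :N] = s
        rhs = np.concatenate([p_t, [0.0]])
        sol = np.linalg.solve(A, rhs)
        q = sol[:N]
    else:
        raise ValueError("kernel must be 'free' or 'periodic'")

    return SourceSinkLayout(positions_um=pos, strengths_m3s=q,
                            domain_um=domain_um, gap_um=gap_um,
                            core_radius_um=core)


def solve_plane_potential(layout: SourceSinkLayout,
                          grid_shape: tuple[int, int],
                          kernel: str = "periodic",
                          fluid: FluidProperties | None = None,
                          flux_scale: float = 1.0):
    """Rasterize the oracle depth-averaged velocity field.

    Returns a :class:`chorioflow.tracer.PlanarVelocityField` on a
    cell-centred grid of the given shape spanning the layout's domain.
    ``flux_scale`` multiplies the strengths (used to calibrate the oracle
    to the lattice solver's measured inlet flux).
    """
    from .tracer import PlanarVelocityField

    nx, ny = grid_shape
    Lx, Ly = layout.domain_um
    spacing_um = Lx / nx
    if abs(Ly / ny - spacing_um) > 1e-9 * spacing_um:
        raise ValueError("grid shape must give square cells")
    xs = (np.arange(nx) + 0.5) * spacing_um
    ys = (np.arange(ny) + 0.5) * spacing_um

    if kernel == "free":
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        u = _depth_avg_velocity_free(layout, pts) * flux_scale
        ux = u[:, 0].reshape(nx, ny)
        uy = u[:, 1].reshape(nx, ny)
    elif kernel == "periodic":
        fluid = fluid or FluidProperties()
        mu = fluid.dynamic_viscosity
        h = layout.gap_um * 1e-6
        dx_m = spacing_um * 1e-6
        sigma = np.zeros((nx, ny))
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        for k in range(layout.positions_um.shape[0]):
            cx, cy = layout.positions_um[k]
            m = ((X - cx)**2 + (Y - cy)**2 <= layout.core_radius_um[k]**2)
            if not m.any():
                ix = int(cx / spacing_um) % nx
                iy = int(cy / spacing_um) % ny
                m = np.zeros((nx, ny), bool)
                m[ix, iy] = True
            sigma[m] += (layout.strengths_m3s[k] * flux_scale
                         / (m.sum() * dx_m**2))
        p = _fft_poisson(-12 * mu / h**3 * sigma, dx_m)
        gpx = (np.roll(p, -1, 0) - np.roll(p, 1, 0)) / (2 * dx_m)
        gpy = (np.roll(p, -1, 1) - np.roll(p, 1, 1)) / (2 * dx_m)
        ux = -(h**2 / (12 * mu)) * gpx
        uy = -(h**2 / (12 * mu)) * gpy
    else:
        raise ValueError("kernel must be 'free' or 'periodic'")
    return PlanarVelocityField(ux=ux, uy=uy, spacing_um=spacing_um,
                               periodic=(kernel == "periodic"))


def divergence(field) -> np.ndarray:
    """Central-difference divergence of a planar field (1/s)."""
    dx_m = field.spacing_um * 1e-6
    dxu = (np.roll(field.ux, -1, 0) - np.roll(field.ux, 1, 0)) / (2 * dx_m)
    dyv = (np.roll(field.uy, -1, 1) - np.roll(field.uy, 1, 1)) / (2 * dx_m)
    return dxu + dyv


# ---------------------------------------------------------------------------
# channel closed forms
# ---------------------------------------------------------------------------

def analytic_poiseuille(channel: AnalyticChannel):
    """Profile, mean velocity and wall shear of plane Poiseuille flow.

    Returns ``(profile, u_mean, tau_wall)`` where ``profile(y)`` evaluates
    ``G y (h - y) / (2 mu)``, ``u_mean = G h^2 / (12 mu)`` and
    ``tau_wall = G h / 2``.
    """
    G = channel.pressure_gradient
    hgt = channel.height_m
    mu = channel.dynamic_viscosity

    def profile(y):
        return G * np.asarray(y) * (hgt - np.asarray(y)) / (2 * mu)

    u_mean = G * hgt**2 / (12 * mu)
    tau_wall = G * hgt / 2
    return profile, u_mean, tau_wall
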