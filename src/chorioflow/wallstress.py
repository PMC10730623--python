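"""Endothelial wall stress from the converged lattice state.

The strain rate is available both by finite differences of the velocity
field and directly from the second moment of the non-equilibrium
populations; the total stress combines the isotropic (pressure) part with
the Newtonian deviatoric closure.  The Cauchy traction on the wall,
``T^(W) = T . N^w``, splits into the endothelial normal stress (its
projection on the wall normal) and the endothelial shear stress (the
tangential remainder) — the mechanical stimulus sensed by the endothelium.

Wall normals are estimated from the gradient of a Gaussian-smoothed copy
of the solid fraction field and point into the solid.  Wall-cell stress is
obtained by linear extrapolation along the inward normal from stress
sampled one and two cells inside the fluid, which is exact for the linear
shear profiles of near-wall laminar flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .engine import equilibrium
from .lattice import D3Q19, LatticeModel
from .units import UnitSystem

__all__ = [
    "WallStressResult",
    "strain_rate_fd",
    "strain_rate_moment",
    "total_stress",
    "estimate_wall_normals",
    "wall_cells_mask",
    "wall_stress",
]


@dataclass
class WallStressResult:
    """Traction decomposition on wall cells.

    ``indices`` is (3, K); ``traction``, ``ens`` and ``ess`` are (3, K)
    vectors in the stress units of the input tensor (Pa when a unit system
    was applied), with ``traction = ens + ess`` exactly and ``ess``
    orthogonal to the normal by construction.
    """

    indices: np.ndarray
    normals: np.ndarray     # (3, K), unit, into solid
    traction: np.ndarray
    ens: np.ndarray
    ess: np.ndarray

    @property
    def ess_magnitude(self) -> np.ndarray:
        return np.sqrt((self.ess**2).sum(axis=0))

    @property
    def ens_magnitude(self) -> np.ndarray:
        return np.sqrt((self.ens**2).sum(axis=0))

    def ess_grid(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Scalar ESS scattered onto the full grid (nan off-wall)."""
        out = np.full(shape, np.nan)
        out[tuple(self.indices)] = self.ess_magnitude
        return out


# ---------------------------------------------------------------------------
# strain rate
# ---------------------------------------------------------------------------

def strain_rate_fd(u: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """S_ab = (d_a u_b + d_b u_a) / 2 by central differences.

    ``u`` is (3, nx, ny, nz); differences are central in the interior and
    one-sided at the array edges (np.gradient).  Units follow ``u`` and
    ``spacing``.
    """
    grads = [np.gradient(u[c], spacing, axis=(0, 1, 2)) for c in range(3)]
    S = np.empty((3, 3) + u.shape[1:])
    for a in range(3):
        for b in range(3):
            S[a, b] = 0.5 * (grads[b][a] + grads[a][b])
    return S


def strain_rate_moment(n: np.ndarray, tau: float,
                       P: np.ndarray | None = None,
                       lattice: LatticeModel | None = None) -> np.ndarray:
    """Strain rate from the second moment of the non-equilibrium populations.

    S_ab = -1 / (2 tau cs2 sum_i n_i) * sum_i e_ia e_ib (n_i - n_i^eq),
    in lattice units (1/step); cells without population are masked to zero.
    """
    lattice = lattice or D3Q19()
    N = n.sum(axis=0)
    valid = N > 0
    if P is not None:
        valid &= P < 1.0
    Nsafe = np.where(valid, N, 1.0)
    u = np.tensordot(lattice.e.astype(float).T, n, axes=(1, 0)) / Nsafe
    u = np.where(valid, u, 0.0)
    neq = equilibrium(Nsafe, u, lattice)
    dn = n - neq
    e = lattice.e.astype(float)
    S = np.empty((3, 3) + n.shape[1:])
    for a in range(3):
        for b in range(3):
            mom = np.tensordot(e[:, a] * e[:, b], dn, axes=(0, 0))
            S[a, b] = np.where(valid,
                               -mom / (2 * tau * lattice.cs2 * Nsafe), 0.0)
    return S


def total_stress(n: np.ndarray, S: np.ndarray,
                 P: np.ndarray | None = None, tau: float = 0.8,
                 lattice: LatticeModel | None = None,
                 units: UnitSystem | None = None) -> np.ndarray:
    """Total stress T_ab = -(sum n cs2 / (1 - P)) delta_ab + (2tau-1) cs2 S.

    The first term is the (negative) absolute lattice pressure, the second
    the Newtonian deviatoric stress.  If ``units`` is given the result is
    converted to Pa (and ``S`` is assumed to be in lattice units).
    """
    lattice = lattice or D3Q19()
    N = n.sum(axis=0)
    if P is None:
        P = np.zeros_like(N)
    frac = np.where(P < 1.0, 1.0 - P, 1.0)
    iso = -N * lattice.cs2 / frac
    T = (2 * tau - 1) * lattice.cs2 * S.copy()
    for a in range(3):
        T[a, a] += iso
    if units is not None:
        T = T * units.pressure_scale
    return T


# ---------------------------------------------------------------------------
# wall geometry
# ---------------------------------------------------------------------------

def wall_cells_mask(P: np.ndarray) -> np.ndarray:
    """Cells on the fluid-solid interface.

    Boundary cells proper (0 < P < 1) plus fluid cells with a face
    neighbour that is solid (sharp-wall geometries have no fractional
    cells).
    """
    frac = (P > 0) & (P < 1)
    solid = P >= 1.0
    near = ndimage.binary_dilation(
        solid, structure=ndimage.generate_binary_structure(3, 1))
    return frac | ((P == 0) & near)


def estimate_wall_normals(P: np.ndarray, sigma: float = 1.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Unit outward wall normals (pointing into the solid) on wall cells.

    The solid fraction is Gaussian-smoothed (sigma in cells) and its
    central-difference gradient normalized.  Returns ``(normals, defined)``
    where ``normals`` is (3, nx, ny, nz) (nan off-wall or where the
    gradient vanishes) and ``defined`` is the boolean validity mask.
    """
    Ps = ndimage.gaussian_filter(P, sigma=sigma, mode="nearest")
    g = np.stack(np.gradient(Ps), axis=0)
    mag = np.sqrt((g**2).sum(axis=0))
    wall = wall_cells_mask(P)
    defined = wall & (mag > 1e-12)
    normals = np.full_like(g, np.nan)
    normals[:, defined] = g[:, defined] / mag[defined]
    return normals, defined


# ---------------------------------------------------------------------------
# wall traction
# ---------------------------------------------------------------------------

def _interp_tensor(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (3, 3, nx, ny, nz) tensor field.

    ``pts`` is (K, 3) in cell coordinates; x-y wrap periodically, z clamps.
    """
    nx, ny, nz = T.shape[2:]
    f = pts.copy()
    f[:, 2] = np.clip(f[:, 2], 0, nz - 1.000001)
    i0 = np.floor(f).astype(np.int64)
    t = f - i0
    out = np.zeros((3, 3, pts.shape[0]))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                ii = (i0[:, 0] + dx) % nx
                jj = (i0[:, 1] + dy) % ny
                kk = np.clip(i0[:, 2] + dz, 0, nz - 1)
                out += w * T[:, :, ii, jj, kk]
    return out


def wall_stress(T: np.ndarray, normals: np.ndarray,
                defined: np.ndarray | None = None,
                P: np.ndarray | None = None,
                extrapolate: bool = True) -> WallStressResult:
    """Cauchy traction and its normal/shear decomposition on wall cells.

    ``T^(W)_a = T_ab N_b``, ``T^(ENS) = (N . T . N) N`` and
    ``T^(ESS) = T^(W) - T^(ENS)``.  With ``extrapolate`` (default) the
    stress entering the Cauchy formula is linearly extrapolated to the
    wall plane from samples one and two cells inside the fluid along the
    inward normal.  For sharp-wall geometries the wall cell is the fluid
    cell hugging the solid and the physical wall (half-way bounce-back)
    sits half a cell beyond its centre; for fractional boundary cells the
    wall passes through the cell itself.  Cells with undefined normals
    are excluded.
    """
    if defined is None:
        defined = np.isfinite(normals).all(axis=0)
    idx = np.argwhere(defined).T          # (3, K)
    nvec = normals[:, defined]            # (3, K)
    if extrapolate:
        base = idx.T.astype(float)
        d1 = base - nvec.T * 1.0
        d2 = base - nvec.T * 2.0
        T1 = _interp_tensor(T, d1)
        T2 = _interp_tensor(T, d2)
        if P is not None:
            offset = np.where(P[tuple(idx)] == 0.0, 0.5, 0.0)
        else:
            offset = np.full(idx.shape[1], 0.5)
        # f(s) sampled at s = 1, 2 cells into the fluid; the wall plane is
        # at s = -offset, so f(-offset) = T1 + (1 + offset) (T1 - T2).
        Tw = T1 + (1.0 + offset) * (T1 - T2)
    else:
        Tw = T[:, :, idx[0], idx[1], idx[2]]
    traction = np.einsum("abk,bk->ak", Tw, nvec)
    tn = np.einsum("ak,ak->k", traction, nvec)
    ens = tn * nvec
    ess = traction - ens
    return WallStressResult(indices=idx, normals=nvec, traction=traction,
                            ens=ens, ess=ess)
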