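"""Numba-compiled collision and streaming kernels.

Arrays are laid out ``n[b, nx, ny, nz]`` (direction-major, z contiguous).
Solid cells (P >= 1) carry zero population and are never updated.  All
three index axes wrap periodically; physical domains close the z extent
with solid capping layers, which makes the z wrap inert there.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def collide_kernel(n, n_post, P, e, w, opp, cs2, tau, a):
    """BGK collision with the population-weighted forcing term.

    n_post[i] = n[i] - (n[i] - n_eq[i]) / tau + F[i], where the equilibrium
    is built from the cell's own zeroth/first moments and
    F[i] = -w[i] * N * (e_i . a) / cs2 (lattice time step = 1).
    """
    b, nx, ny, nz = n.shape
    inv_tau = 1.0 / tau
    cs4 = cs2 * cs2
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if P[x, y, z] >= 1.0:
                    for i in range(b):
                        n_post[i, x, y, z] = 0.0
                    continue
                N = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(b):
                    ni = n[i, x, y, z]
                    N += ni
                    mx += e[i, 0] * ni
                    my += e[i, 1] * ni
                    mz += e[i, 2] * ni
                if N <= 0.0:
                    for i in range(b):
                        n_post[i, x, y, z] = 0.0
                    continue
                ux = mx / N
                uy = my / N
                uz = mz / N
                usq = ux * ux + uy * uy + uz * uz
                for i in range(b):
                    eu = e[i, 0] * ux + e[i, 1] * uy + e[i, 2] * uz
                    neq = N * w[i] * (1.0 + eu / cs2
                                      + eu * eu / (2.0 * cs4)
                                      - usq / (2.0 * cs2))
                    ea = e[i, 0] * a[0] + e[i, 1] * a[1] + e[i, 2] * a[2]
                    F = -w[i] * N * ea / cs2
                    n_post[i, x, y, z] = (n[i, x, y, z]
                                          - inv_tau * (n[i, x, y, z] - neq)
                                          + F)


@njit(cache=True, fastmath=True)
def stream_kernel(n_post, n_new, P, e, opp):
    """Volumetric streaming (gather form) with partial bounce-back.

    Each non-solid cell pulls along the reverse direction.  If the upwind
    neighbour is strictly less solid the pulled population is rescaled by
    the fluid-volume ratio; otherwise the plain pull is augmented by the
    volumetric bounce-back of the cell's own opposite post-collision
    population, weighted by the solidity jump.  The two branches are
    exclusive, which conserves mass pairwise for arbitrary P.
    """
    b, nx, ny, nz = n_post.shape
    for i in range(b):
        ex = e[i, 0]
        ey = e[i, 1]
        ez = e[i, 2]
        io = opp[i]
        for x in range(nx):
            xn = (x - ex) % nx
            for y in range(ny):
                yn = (y - ey) % ny
                for z in range(nz):
                    Pl = P[x, y, z]
                    if Pl >= 1.0:
                        n_new[i, x, y, z] = 0.0
                        continue
                    zn = (z - ez) % nz
                    Pn = P[xn, yn, zn]
                    pulled = n_post[i, xn, yn, zn]
                    if Pn < Pl:
                        n_new[i, x, y, z] = (1.0 - Pl) / (1.0 - Pn) * pulled
                    else:
                        n_new[i, x, y, z] = (pulled
                                             + (Pn - Pl) / (1.0 - Pl)
                                             * n_post[io, x, y, z])
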