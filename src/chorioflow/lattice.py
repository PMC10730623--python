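"""Discrete velocity sets for the lattice Boltzmann solver.

A :class:`LatticeModel` bundles the discrete velocities ``e_i``, quadrature
weights ``w_i``, lattice sound speed, and the opposite-direction permutation
used by bounce-back.  Velocities are stored as 3-component integer vectors so
the same streaming kernel serves both the 3-D (D3Q19) and the plane (D2Q9,
embedded with ``e_z = 0``) models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LatticeModel", "D3Q19", "D2Q9"]


@dataclass(frozen=True)
class LatticeModel:
    """A discrete-velocity (DnQb) lattice.

    Attributes
    ----------
    name : str
        Conventional name, e.g. ``"D3Q19"``.
    e : (b, 3) int ndarray
        Discrete velocity vectors in lattice units (cells per step).
    w : (b,) float ndarray
        Quadrature weights; sum to one.
    cs2 : float
        Squared lattice sound speed (1/3 for the standard models).
    opp : (b,) int ndarray
        Index permutation with ``e[opp[i]] == -e[i]``.
    """

    name: str
    e: np.ndarray
    w: np.ndarray
    cs2: float
    opp: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        e = np.ascontiguousarray(np.asarray(self.e, dtype=np.int64))
        w = np.ascontiguousarray(np.asarray(self.w, dtype=np.float64))
        if e.ndim != 2 or e.shape[1] != 3 or e.shape[0] != w.shape[0]:
            raise ValueError("e must be (b, 3) and match w")
        opp = np.empty(e.shape[0], dtype=np.int64)
        for i, ei in enumerate(e):
            matches = np.flatnonzero((e == -ei).all(axis=1))
            if matches.size != 1:
                raise ValueError("velocity set is not closed under negation")
            opp[i] = matches[0]
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "opp", opp)
        # Quadrature identities required of any admissible lattice.
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if not np.allclose(w @ e.astype(float), 0.0):
            raise ValueError("first weight moment must vanish")
        second = np.einsum("i,ia,ib->ab", w, e.astype(float), e.astype(float))
        # D2Q9 embedded in 3-D has a zero zz block; check only active axes.
        active = np.flatnonzero(np.abs(e).sum(axis=0) > 0)
        if not np.allclose(second[np.ix_(active, active)],
                           self.cs2 * np.eye(active.size)):
            raise ValueError("second weight moment must equal cs2 * identity")

    @property
    def b(self) -> int:
        """Number of discrete velocities."""
        return int(self.e.shape[0])


def D3Q19() -> LatticeModel:
    """The 19-velocity 3-D lattice (rest + 6 axial + 12 face-diagonal)."""
    e = [[0, 0, 0]]
    e += [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    e += [
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ]
    w = [1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12
    return LatticeModel("D3Q19", np.array(e), np.array(w), 1.0 / 3.0)


def D2Q9() -> LatticeModel:
    """The 9-velocity plane lattice, embedded with ``e_z = 0``."""
    e = [[0, 0, 0],
         [1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0],
         [1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]]
    w = [4.0 / 9.0] + [1.0 / 9.0] * 4 + [1.0 / 36.0] * 4
    return LatticeModel("D2Q9", np.array(e), np.array(w), 1.0 / 3.0)
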