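"""D3Q19 lattice definition and kinetic-moment primitives.

The solver evolves 19 particle populations per voxel.  The velocity set
contains the rest vector, the six axis directions and the twelve face
diagonals; the associated weights (1/3, 1/18, 1/36) satisfy the isotropy
conditions required for the second-order equilibrium to recover the
incompressible Navier-Stokes equations at low Mach number.  All quantities
in this module are in lattice units (dx = dt = 1, lattice sound speed
cs = 1/sqrt(3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LatticeModel",
    "D3Q19",
    "equilibrium_distribution",
    "macroscopic_moments",
]


def _d3q19_vectors() -> np.ndarray:
    vecs = [(0, 0, 0)]
    for a in range(3):
        for s in (1, -1):
            v = [0, 0, 0]
            v[a] = s
            vecs.append(tuple(v))
    for a in range(3):
        b = (a + 1) % 3
        for sa in (1, -1):
            for sb in (1, -1):
                v = [0, 0, 0]
                v[a] = sa
                v[b] = sb
                vecs.append(tuple(v))
    return np.array(vecs, dtype=np.int64)


@dataclass(frozen=True)
class LatticeModel:
    """The discrete velocity set, weights and derived index tables."""

    velocities: np.ndarray = field(default_factory=_d3q19_vectors)

    @property
    def q(self) -> int:
        return len(self.velocities)

    @property
    def weights(self) -> np.ndarray:
        w = np.empty(self.q)
        norm2 = (self.velocities**2).sum(axis=1)
        w[norm2 == 0] = 1.0 / 3.0
        w[norm2 == 1] = 1.0 / 18.0
        w[norm2 == 2] = 1.0 / 36.0
        return w

    @property
    def sound_speed_lattice(self) -> float:
        """Lattice speed of sound, 1/sqrt(3)."""
        return 1.0 / np.sqrt(3.0)

    @property
    def opposite(self) -> np.ndarray:
        """Index of the negated velocity for each direction."""
        c = self.velocities
        opp = np.empty(self.q, dtype=np.int64)
        for i, v in enumerate(c):
            (j,) = np.nonzero((c == -v).all(axis=1))[0]
            opp[i] = j
        return opp


D3Q19 = LatticeModel()

# Module-level constants used by the hot loops.
_C = D3Q19.velocities
_CF = _C.astype(np.float64)
_W = D3Q19.weights
_OPP = D3Q19.opposite
_CS2 = 1.0 / 3.0


def equilibrium_distribution(density, velocity):
    """Second-order BGK equilibrium populations.

    Parameters
    ----------
    density : float or (n,) array
        Fluid density rho in lattice units; must be positive.
    velocity : (3,) or (3, n) array
        Fluid velocity in lattice units; must satisfy |u| < 1/sqrt(3).

    Returns
    -------
    (19,) or (19, n) array of equilibrium populations
        f_i = w_i rho [1 + c.u/cs^2 + (c.u)^2/(2 cs^4) - u^2/(2 cs^2)].
    """
    rho = np.asarray(density, dtype=np.float64)
    u = np.asarray(velocity, dtype=np.float64)
    if np.any(rho <= 0):
        raise ValueError("equilibrium requires positive density")
    scalar = u.ndim == 1
    if scalar:
        u = u[:, None]
        rho = np.atleast_1d(rho)
    cu = _CF @ u  # (19, n)
    usq = (u * u).sum(axis=0)  # (n,)
    feq = _W[:, None] * rho[None, :] * (
        1.0 + cu / _CS2 + 0.5 * cu**2 / _CS2**2 - 0.5 * usq[None, :] / _CS2
    )
    return feq[:, 0] if scalar else feq


def macroscopic_moments(populations):
    """Density and velocity from populations.

    rho = sum_i f_i,  u = sum_i c_i f_i / rho.  Raises on non-positive
    density, which signals a corrupted or unstable state.
    """
    f = np.asarray(populations, dtype=np.float64)
    scalar = f.ndim == 1
    if scalar:
        f = f[:, None]
    rho = f.sum(axis=0)
    if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
        raise FloatingPointError("non-positive or non-finite density")
    mom = _CF.T @ f  # (3, n)
    u = mom / rho[None, :]
    if scalar:
        return float(rho[0]), u[:, 0]
    return rho, u
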