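"""Boundary conditions: interpolated bounce-back walls, velocity inlet,
open outlet, and the inlet warm-up ramp.

Three boundary treatments close the lattice-Boltzmann update:

* **Bouzidi walls** — linearly interpolated bounce-back using the sub-voxel
  wall fraction q of each cut link (two branches, q < 1/2 and q >= 1/2);
  at q = 1/2 it reduces to simple bounce-back.  Walls are rigid, so no
  moving-wall momentum terms appear.
* **Ladd velocity inlet** — bounce-back augmented with a momentum term,
  imposing a time-dependent Dirichlet velocity.  The imposed profile is
  parabolic in the normalized wall distance d of each inlet site,
  u(d) = u_c (2d - d^2): zero at the wall, the measured trace velocity
  u_c at the site furthest from any wall.
* **Nash open outlet** — mixed Dirichlet-Neumann condition: in-plane
  velocity zero, zero normal gradient of the normal velocity (first-order
  finite difference along the plane normal), and prescribed density rho0;
  the unknown incoming populations are reconstructed from the equilibrium
  at (rho0, u_n n).

All update functions operate on the engine's prepared link tables and
write the unknown post-stream populations in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PlaneSpec, VesselGeometry, inlet_profile_map
from .lattice import _CF, _CS2, _OPP, _W
from .waveform import VelocityTrace

__all__ = [
    "InletSpec",
    "OutletSpec",
    "WallLinkGroup",
    "warmup_ramp",
    "parabolic_profile",
    "bouzidi_wall_update",
    "ladd_inlet_update",
    "nash_outlet_update",
]


@dataclass
class WallLinkGroup:
    """Cut links toward the wall along one lattice direction j."""

    direction: int  # j, pointing from fluid site toward the wall
    sites: np.ndarray  # fluid ids
    q: np.ndarray  # wall fraction in (0, 1]
    upstream: np.ndarray  # fluid id of site - c_j, or -1 if unavailable


@dataclass
class InletSpec:
    """Velocity-inlet description bound to one inlet plane."""

    plane: PlaneSpec
    trace: VelocityTrace
    site_ids: np.ndarray  # fluid ids of inlet-layer sites
    profile_map: np.ndarray  # normalized wall distance d in [0, 1] per site
    center_site: int  # index into site_ids of the profile center (d = 1)
    warmup_duration: float = 0.0
    velocity_scale: float = 1.0  # reduced-velocity factor s
    # per-link tables (parallel arrays)
    link_dirs: np.ndarray = None  # j of each cut link
    link_sites: np.ndarray = None  # index into site_ids
    custom_profile: object = None  # callable (d, t) -> speeds, overrides parabola

    @property
    def inward(self) -> np.ndarray:
        """Unit vector pointing from the inlet plane into the domain."""
        return -self.plane.normal

    def target_speeds(self, t: float) -> np.ndarray:
        """Imposed speed of every inlet site at time t [m/s]."""
        if self.custom_profile is not None:
            speeds = np.asarray(self.custom_profile(self.profile_map, t), float)
        else:
            u_c = float(self.trace(t)) * self.velocity_scale
            speeds = parabolic_profile(self, u_c)
        return speeds * warmup_ramp(t, self.warmup_duration)


@dataclass
class OutletSpec:
    """Open-outlet description bound to one outlet plane."""

    plane: PlaneSpec
    rho0: float = 1.0  # prescribed lattice density
    site_ids: np.ndarray = None  # fluid ids of outlet-boundary sites
    interior_ids: np.ndarray = None  # fluid id used for the normal-gradient stencil
    link_dirs: np.ndarray = None
    link_sites: np.ndarray = None  # index into site_ids

    def __post_init__(self):
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")


def warmup_ramp(t: float, warmup_duration: float) -> float:
    """Half-cosine ramp: 0 at t = 0, 1 at t >= warmup_duration.

    Applied multiplicatively to the inlet trace so the flow starts from
    rest without shock waves.  C^1 at both ends.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if warmup_duration <= 0 or t >= warmup_duration:
        return 1.0
    return 0.5 * (1.0 - np.cos(np.pi * t / warmup_duration))


def parabolic_profile(inlet: InletSpec, center_speed: float) -> np.ndarray:
    """Per-site speeds u_c (2d - d^2) for the inlet's profile map.

    The unique quadratic in normalized wall distance with u(0) = 0,
    u(1) = center_speed and zero slope at the center.
    """
    d = inlet.profile_map
    return center_speed * (2.0 * d - d * d)


def make_inlet(
    geometry: VesselGeometry,
    plane: PlaneSpec,
    trace: VelocityTrace,
    fluid_id_of_flat: np.ndarray,
    warmup_duration: float = 0.0,
    velocity_scale: float = 1.0,
    custom_profile=None,
) -> InletSpec:
    """Bind an inlet plane to a velocity trace and build its link tables."""
    ijk, d, center = inlet_profile_map(geometry, plane)
    flat = np.ravel_multi_index(ijk.T, geometry.fluid_mask.shape)
    site_ids = fluid_id_of_flat[flat]
    pos_of_flat = {f: n for n, f in enumerate(flat)}
    plane_idx = geometry.planes.index(plane)
    sel = geometry.link_plane == plane_idx
    link_sites = np.array(
        [pos_of_flat[f] for f in geometry.link_site[sel]], dtype=np.int64
    )
    return InletSpec(
        plane=plane,
        trace=trace,
        site_ids=site_ids,
        profile_map=d,
        center_site=center,
        warmup_duration=warmup_duration,
        velocity_scale=velocity_scale,
        link_dirs=geometry.link_dir[sel].copy(),
        link_sites=link_sites,
        custom_profile=custom_profile,
    )


def make_outlet(
    geometry: VesselGeometry,
    plane: PlaneSpec,
    fluid_id_of_flat: np.ndarray,
    rho0: float = 1.0,
) -> OutletSpec:
    """Bind an outlet plane and locate interior stencil neighbors."""
    plane_idx = geometry.planes.index(plane)
    sel = geometry.link_plane == plane_idx
    if not sel.any():
        raise ValueError(f"outlet plane {plane.label!r} has no boundary links")
    flats = np.unique(geometry.link_site[sel])
    site_ids = fluid_id_of_flat[flats]
    shape = geometry.fluid_mask.shape
    ijk = np.stack(np.unravel_index(flats, shape), axis=1)
    # lattice directions ranked by alignment with the inward normal
    c = _CF[1:]
    align = (c / np.linalg.norm(c, axis=1)[:, None]) @ (-plane.normal)
    order = 1 + np.argsort(-align)
    interior = np.empty(len(flats), dtype=np.int64)
    from .lattice import _C

    for n, site in enumerate(ijk):
        interior[n] = site_ids[n]  # fallback: the site itself (zero gradient)
        for j in order:
            if align[j - 1] <= 0:
                break
            nbr = site + _C[j]
            if np.all(nbr >= 0) and np.all(nbr < shape):
                fid = fluid_id_of_flat[np.ravel_multi_index(tuple(nbr), shape)]
                if fid >= 0:
                    interior[n] = fid
                    break
    pos_of_flat = {f: n for n, f in enumerate(flats)}
    link_sites = np.array(
        [pos_of_flat[f] for f in geometry.link_site[sel]], dtype=np.int64
    )
    return OutletSpec(
        plane=plane,
        site_ids=site_ids,
        interior_ids=interior,
        link_dirs=geometry.link_dir[sel].copy(),
        link_sites=link_sites,
    )


def bouzidi_wall_update(f_new, f_post, groups) -> None:
    """Apply interpolated bounce-back for all wall-cut links.

    For a link from fluid site x toward the wall along c_j with fraction q
    (f* = post-collision populations):

        q < 1/2:  f_jbar(x) = 2 q f*_j(x) + (1 - 2q) f*_j(x - c_j)
        q >= 1/2: f_jbar(x) = f*_j(x) / (2q) + (2q - 1)/(2q) f*_jbar(x)

    Links whose upstream site is unavailable fall back to simple
    bounce-back (the q = 1/2 degeneracy).
    """
    for g in groups:
        j = g.direction
        i = _OPP[j]
        fj = f_post[j, g.sites]
        near = g.q < 0.5
        has_up = g.upstream >= 0
        use_interp = near & has_up
        out = fj.copy()  # default: simple bounce-back
        if use_interp.any():
            q = g.q[use_interp]
            out[use_interp] = (
                2.0 * q * fj[use_interp]
                + (1.0 - 2.0 * q) * f_post[j, g.upstream[use_interp]]
            )
        far = ~near
        if far.any():
            q = g.q[far]
            out[far] = fj[far] / (2.0 * q) + (2.0 * q - 1.0) / (2.0 * q) * f_post[
                i, g.sites[far]
            ]
        f_new[i, g.sites] = out


def ladd_inlet_update(f_new, f_post, inlet: InletSpec, u_lattice: np.ndarray,
                      rho0: float = 1.0) -> None:
    """Impose the inlet velocity via bounce-back plus momentum term.

    ``u_lattice`` is the (3, n_sites) target velocity of each inlet site in
    lattice units (already ramped/scaled).  For each cut link along c_j:

        f_jbar(x) = f*_j(x) - 2 w_j rho0 (c_j . u) / cs^2
    """
    j = inlet.link_dirs
    s = inlet.site_ids[inlet.link_sites]
    cu = np.einsum("la,al->l", _CF[j], u_lattice[:, inlet.link_sites])
    f_new[_OPP[j], s] = f_post[j, s] - 2.0 * _W[j] * rho0 * cu / _CS2


def nash_outlet_update(f_new, outlet: OutletSpec, u_fluid: np.ndarray,
                       f_neq: np.ndarray) -> None:
    """Reconstruct unknown outlet populations from (rho0, u_n n-hat).

    ``u_fluid`` is the (3, nf) pre-collision velocity field; the normal
    velocity is taken from the interior stencil neighbor (first-order
    zero-gradient extrapolation along the normal), the in-plane component
    is dropped, and the density is prescribed at rho0.  The unknown
    populations are set to the equilibrium at (rho0, u_n n-hat) plus the
    interior neighbor's non-equilibrium part (second-order open-boundary
    reconstruction), which suppresses spurious in-plane flow at the
    boundary slice.
    """
    n_hat = outlet.plane.normal
    u_n = n_hat @ u_fluid[:, outlet.interior_ids]  # (n_sites,)
    u = np.outer(n_hat, u_n)  # (3, n_sites)
    usq = (u * u).sum(axis=0)
    j = outlet.link_dirs
    i = _OPP[j]
    s_local = outlet.link_sites
    cu = np.einsum("la,al->l", _CF[i], u[:, s_local])
    feq = _W[i] * outlet.rho0 * (
        1.0 + cu / _CS2 + 0.5 * cu**2 / _CS2**2 - 0.5 * usq[s_local] / _CS2
    )
    f_new[i, outlet.site_ids[s_local]] = feq + f_neq[
        i, outlet.interior_ids[s_local]
    ]
    # enforce the prescribed density exactly: rescale the full population
    # vector of each outlet boundary site to sum to rho0 (velocity is
    # preserved; this anchors the static pressure and damps acoustic
    # feedback between the open ends)
    rho_site = f_new[:, outlet.site_ids].sum(axis=0)
    f_new[:, outlet.site_ids] *= outlet.rho0 / rho_site
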