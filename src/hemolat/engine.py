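"""D3Q19 BGK lattice-Boltzmann engine on voxelized vessel geometries.

One time step is: compute moments, relax toward the second-order
equilibrium with a per-site relaxation parameter tau (constant for a
Newtonian fluid, recomputed each step from the local shear rate for the
Carreau-Yasuda fluid), stream along lattice links, then close the unknown
incoming populations at walls (Bouzidi), inlets (Ladd) and outlets (Nash).

The local shear rate is estimated from the second moment of the
non-equilibrium populations,

    S_ab = -3 / (2 tau rho) Pi_neq_ab,   gamma_dot = sqrt(2 S:S),

the conventional lattice-Boltzmann estimator; it requires no finite
differences, so Newtonian and shear-thinning runs use identical
machinery.  The Carreau-Yasuda coupling lags by one step (tau is updated
from the previous step's shear rate) and tau is clamped to
[0.5 + 1e-6, 10] with a logged warning on clamping.

Fields are stored sparsely as (19, n_fluid) float64 arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import boundaries as bc
from .geometry import LINK_WALL
from .lattice import _C, _CF, equilibrium_distribution, macroscopic_moments
from .rheology import RheologySpec
from .units import UnitSystem, relaxation_from_viscosity

__all__ = [
    "SimulationState",
    "LBMEngine",
    "PeriodicDomain",
    "StabilityError",
    "local_shear_rate",
    "collide_and_stream",
]

logger = logging.getLogger(__name__)

TAU_MIN = 0.5 + 1e-6
TAU_MAX = 10.0

# index pairs for the 6 independent components of a symmetric 3x3 tensor
_SYM_PAIRS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_SYM_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])  # off-diagonals count twice
_CC = np.stack([_CF[:, a] * _CF[:, b] for a, b in _SYM_PAIRS], axis=0)  # (6, 19)


class StabilityError(RuntimeError):
    pass


@dataclass
class SimulationState:
    """Populations plus derived fields on the fluid sites."""

    populations: np.ndarray  # (19, nf)
    density: np.ndarray  # (nf,)
    velocity: np.ndarray  # (3, nf) lattice units
    tau_hat: np.ndarray | float
    time_step_index: int = 0

    @property
    def mass(self) -> float:
        return float(self.populations.sum())


class PeriodicDomain:
    """Fully periodic box (no boundaries); used for closed-domain checks."""

    def __init__(self, shape, unit: UnitSystem):
        self.fluid_mask = np.ones(shape, dtype=bool)
        self.unit = unit
        self.origin = np.zeros(3)
        self.planes = []
        self.link_site = np.empty(0, np.int64)
        self.link_dir = np.empty(0, np.int64)
        self.link_kind = np.empty(0, np.int64)
        self.link_plane = np.empty(0, np.int64)
        self.link_q = np.empty(0)
        self.periodic = True

    @property
    def shape(self):
        return self.fluid_mask.shape

    @property
    def n_fluid(self):
        return int(self.fluid_mask.size)


def local_shear_rate(populations, tau_hat, unit: UnitSystem):
    """Shear rate [1/s] from the non-equilibrium momentum flux.

    Accepts a single 19-vector or a (19, n) batch.  Tiny negative
    round-off under the square root is clamped to zero.
    """
    f = np.asarray(populations, dtype=np.float64)
    scalar = f.ndim == 1
    if scalar:
        f = f[:, None]
    rho, u = macroscopic_moments(f)
    feq = equilibrium_distribution(rho, u)
    pi_neq = _CC @ (f - feq)  # (6, n)
    ssum = (_SYM_MULT[:, None] * pi_neq**2).sum(axis=0)
    tau = np.asarray(tau_hat, dtype=np.float64)
    gdot_lat = 3.0 / (2.0 * tau * rho) * np.sqrt(np.maximum(2.0 * ssum, 0.0))
    gdot = gdot_lat / unit.dt
    return float(gdot[0]) if scalar else gdot


class LBMEngine:
    """Time-stepping engine bound to one geometry, unit system and rheology."""

    def __init__(
        self,
        geometry,
        rheology: RheologySpec,
        rho0: float = 1.0,
        ma_guard: float = 0.1,
        allow_high_mach: bool = False,
    ):
        self.geometry = geometry
        self.unit: UnitSystem = geometry.unit
        self.rheology = rheology
        self.rho0 = float(rho0)
        self.ma_guard = ma_guard
        self.allow_high_mach = allow_high_mach
        self.inlets: list[bc.InletSpec] = []
        self.outlets: list[bc.OutletSpec] = []
        self.clamp_events = 0
        self._build_tables()
        self._init_tau()
        self.state = self._equilibrium_state()

    # -- setup -------------------------------------------------------------

    def _build_tables(self):
        mask = self.geometry.fluid_mask
        shape = mask.shape
        self.fluid_idx = np.argwhere(mask)
        nf = len(self.fluid_idx)
        self.nf = nf
        self.fid_of_flat = np.full(mask.size, -1, dtype=np.int64)
        flat = np.ravel_multi_index(self.fluid_idx.T, shape)
        self.fid_of_flat[flat] = np.arange(nf)
        periodic = getattr(self.geometry, "periodic", False)

        src = np.full((19, nf), -1, dtype=np.int64)
        src[0] = np.arange(nf)
        for i in range(1, 19):
            nbr = self.fluid_idx - _C[i]
            if periodic:
                nbr = nbr % np.array(shape)
                src[i] = self.fid_of_flat[np.ravel_multi_index(nbr.T, shape)]
            else:
                ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
                clipped = np.clip(nbr, 0, np.array(shape) - 1)
                fids = self.fid_of_flat[np.ravel_multi_index(clipped.T, shape)]
                src[i] = np.where(ok, fids, -1)
        self.src = src

        # group wall links by direction; attach upstream sites for Bouzidi
        g = self.geometry
        self.wall_groups = []
        wall = g.link_kind == LINK_WALL
        for j in range(1, 19):
            sel = wall & (g.link_dir == j)
            if not sel.any():
                continue
            sites = self.fid_of_flat[g.link_site[sel]]
            up_idx = self.fluid_idx[sites] - _C[j]
            ok = np.all((up_idx >= 0) & (up_idx < shape), axis=1)
            clipped = np.clip(up_idx, 0, np.array(shape) - 1)
            up = np.where(
                ok, self.fid_of_flat[np.ravel_multi_index(clipped.T, shape)], -1
            )
            self.wall_groups.append(
                bc.WallLinkGroup(
                    direction=j, sites=sites, q=g.link_q[sel].copy(), upstream=up
                )
            )

    def _init_tau(self):
        unit = self.unit
        if self.rheology.model == "newtonian":
            nu = self.rheology.eta / unit.rho_ref
            tau = relaxation_from_viscosity(nu, unit)
            if tau <= 0.5:
                raise StabilityError(f"Newtonian tau = {tau} <= 0.5")
            self.tau = tau
        else:
            # start from the zero-shear plateau; updated per site each step
            nu0 = self.rheology.eta0 / unit.rho_ref
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tau0 = relaxation_from_viscosity(nu0, unit)
            self.tau = np.full(self.nf, np.clip(tau0, TAU_MIN, TAU_MAX))

    def _equilibrium_state(self) -> SimulationState:
        rho = np.full(self.nf, self.rho0)
        u = np.zeros((3, self.nf))
        f = equilibrium_distribution(rho, u)
        return SimulationState(
            populations=f, density=rho, velocity=u, tau_hat=self.tau, time_step_index=0
        )

    def initialize(self, density, velocity) -> SimulationState:
        """Reset the state to the equilibrium of given macroscopic fields.

        ``density``: scalar or (nf,); ``velocity``: (3,) or (3, nf), in
        lattice units.
        """
        rho = np.broadcast_to(np.asarray(density, float), (self.nf,)).copy()
        u = np.broadcast_to(
            np.asarray(velocity, float).reshape(3, -1), (3, self.nf)
        ).copy()
        f = equilibrium_distribution(rho, u)
        self.state = SimulationState(
            populations=f, density=rho, velocity=u, tau_hat=self.tau,
            time_step_index=0,
        )
        return self.state

    # -- boundary registration --------------------------------------------

    def add_inlet(self, plane, trace, warmup_duration=0.0, velocity_scale=1.0,
                  custom_profile=None) -> bc.InletSpec:
        inlet = bc.make_inlet(
            self.geometry, plane, trace, self.fid_of_flat,
            warmup_duration=warmup_duration, velocity_scale=velocity_scale,
            custom_profile=custom_profile,
        )
        peak = float(np.abs(trace.velocities).max()) * velocity_scale
        u_lat = self.unit.to_lattice(peak, "velocity")
        mach = u_lat * np.sqrt(3.0)
        if mach > self.ma_guard and not self.allow_high_mach:
            raise StabilityError(
                f"peak inlet velocity implies Ma = {mach:.3f} > guard "
                f"{self.ma_guard}; refusing to start (pass allow_high_mach "
                "to override)"
            )
        self.inlets.append(inlet)
        return inlet

    def add_outlet(self, plane, rho0=None) -> bc.OutletSpec:
        outlet = bc.make_outlet(
            self.geometry, plane, self.fid_of_flat,
            rho0=self.rho0 if rho0 is None else rho0,
        )
        self.outlets.append(outlet)
        return outlet

    # -- stepping ----------------------------------------------------------

    @property
    def time(self) -> float:
        """Physical time [s] of the current state."""
        return self.state.time_step_index * self.unit.dt

    def _update_tau_cy(self, gdot_phys: np.ndarray):
        eta = self.rheology.viscosity(gdot_phys)
        nu_lat = self.unit.to_lattice(eta / self.unit.rho_ref, "kinematic_viscosity")
        tau = 0.5 + 3.0 * nu_lat
        clamped = (tau < TAU_MIN) | (tau > TAU_MAX)
        n_clamped = int(clamped.sum())
        if n_clamped:
            if self.clamp_events == 0:
                logger.warning(
                    "clamping tau at %d site(s) to [%g, %g]", n_clamped, TAU_MIN, TAU_MAX
                )
            self.clamp_events += n_clamped
        self.tau = np.clip(tau, TAU_MIN, TAU_MAX)

    def step(self) -> SimulationState:
        """Advance one lattice time step (collide, stream, boundaries)."""
        st = self.state
        f = st.populations
        try:
            rho, u = macroscopic_moments(f)
        except FloatingPointError as err:
            raise StabilityError(
                f"invalid state at step {st.time_step_index}: {err}"
            ) from err
        feq = equilibrium_distribution(rho, u)
        fneq = f - feq

        if self.rheology.model == "carreau_yasuda":
            pi_neq = _CC @ fneq
            ssum = (_SYM_MULT[:, None] * pi_neq**2).sum(axis=0)
            gdot_lat = 3.0 / (2.0 * np.asarray(self.tau) * rho) * np.sqrt(
                np.maximum(2.0 * ssum, 0.0)
            )
            self._update_tau_cy(gdot_lat / self.unit.dt)

        tau = self.tau
        f_post = f - fneq / tau

        f_new = np.empty_like(f)
        for i in range(19):
            f_new[i] = f_post[i].take(np.maximum(self.src[i], 0))
        # close unknown incoming populations
        bc.bouzidi_wall_update(f_new, f_post, self.wall_groups)
        t_new = (st.time_step_index + 1) * self.unit.dt
        for inlet in self.inlets:
            speeds = inlet.target_speeds(t_new)
            u_lat = self.unit.to_lattice(speeds, "velocity")
            u_target = np.outer(inlet.inward, u_lat)
            bc.ladd_inlet_update(f_new, f_post, inlet, u_target, rho0=self.rho0)
        for outlet in self.outlets:
            bc.nash_outlet_update(f_new, outlet, u, fneq)

        self.state = SimulationState(
            populations=f_new,
            density=rho,
            velocity=u,
            tau_hat=tau,
            time_step_index=st.time_step_index + 1,
        )
        return self.state

    def run(self, n_steps: int, callback=None, callback_stride: int = 1):
        """Advance ``n_steps``, optionally invoking ``callback(engine)``."""
        for _ in range(n_steps):
            self.step()
            if callback is not None and self.state.time_step_index % callback_stride == 0:
                callback(self)
        return self.state

    # -- field access ------------------------------------------------------

    def refresh_moments(self):
        """Recompute density/velocity of the *current* populations."""
        rho, u = macroscopic_moments(self.state.populations)
        self.state.density = rho
        self.state.velocity = u
        return rho, u

    def velocity_field(self) -> np.ndarray:
        """(3, nx, ny, nz) velocity in m/s; NaN outside the fluid."""
        self.refresh_moments()
        shape = self.geometry.fluid_mask.shape
        out = np.full((3,) + shape, np.nan)
        u_phys = self.unit.to_physical(self.state.velocity, "velocity")
        idx = self.fluid_idx
        out[:, idx[:, 0], idx[:, 1], idx[:, 2]] = u_phys
        return out

    def density_field(self) -> np.ndarray:
        """(nx, ny, nz) lattice density; NaN outside the fluid."""
        self.refresh_moments()
        shape = self.geometry.fluid_mask.shape
        out = np.full(shape, np.nan)
        idx = self.fluid_idx
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = self.state.density
        return out

    def shear_rate_field(self) -> np.ndarray:
        """(nf,) shear rate [1/s] of the current state."""
        return local_shear_rate(self.state.populations, self.tau, self.unit)

    def max_mach(self) -> float:
        self.refresh_moments()
        umax = float(np.linalg.norm(self.state.velocity, axis=0).max())
        return umax * np.sqrt(3.0)


def collide_and_stream(
    engine: LBMEngine, n_steps: int = 1
) -> SimulationState:
    """Functional alias: advance the engine's state by ``n_steps``."""
    return engine.run(n_steps)
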