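"""Measurement-plane extraction and validation statistics.

The validation surface of the workflow: velocity fields are interpolated
onto 2-D measurement planes, the peak velocity per plane over the cardiac
cycle (vmax) is compared with the Doppler-measured peak through the
relative-difference statistic

    d_r = 100 (v_max_sim - v_max_TCD) / v_max_TCD  [%],

reduced-velocity runs are rescaled by 1/s before comparison, and the
Reynolds / Womersley / Mach numbers that govern the flow regime — and the
impossibility of preserving both Re and alpha under velocity scaling at
fixed geometry and cardiac frequency — are computed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import PlaneSpec, VesselGeometry
from .units import UnitSystem, speed_of_sound

__all__ = [
    "PlaneSampler",
    "PlaneProfile",
    "ComparisonRecord",
    "DimensionlessSummary",
    "ScalingReport",
    "sample_plane",
    "vmax_of_profile",
    "relative_difference",
    "rescale_extracted",
    "wall_shear_stress",
    "differential_pressure",
    "dimensionless_numbers",
    "scaling_feasibility",
    "step_count",
]


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


class PlaneSampler:
    """Trilinear interpolation of voxel fields onto a plane grid.

    The grid pitch equals the voxel size dx; grid positions whose
    trilinear stencil contains solid voxels use fluid-only renormalized
    weights, and positions with no fluid support at all are NaN (flagged
    distinctly from zero velocity).
    """

    def __init__(self, geometry: VesselGeometry, plane: PlaneSpec):
        self.geometry = geometry
        self.plane = plane
        dx = geometry.unit.dx
        mask = geometry.fluid_mask
        idx = np.argwhere(mask)
        centers = geometry.voxel_centers(idx)
        signed = (centers - plane.location) @ plane.normal
        near = np.abs(signed) <= dx
        if not near.any():
            raise ValueError(f"plane {plane.label!r} does not intersect the fluid")
        e1, e2 = _plane_basis(plane.normal)
        rel = centers[near] - plane.location
        a, b = rel @ e1, rel @ e2
        amin, amax = a.min() - dx, a.max() + dx
        bmin, bmax = b.min() - dx, b.max() + dx
        na = int(np.ceil((amax - amin) / dx)) + 1
        nb = int(np.ceil((bmax - bmin) / dx)) + 1
        ga, gb = np.meshgrid(
            amin + np.arange(na) * dx, bmin + np.arange(nb) * dx, indexing="ij"
        )
        pts = (
            plane.location
            + np.multiply.outer(ga, e1)
            + np.multiply.outer(gb, e2)
        )  # (na, nb, 3)
        self.grid_shape = (na, nb)
        self.axes = (e1, e2)
        # trilinear stencil
        g = (pts - geometry.origin) / dx - 0.5
        base = np.floor(g).astype(np.int64)
        frac = g - base
        shape = np.array(mask.shape)
        corners, weights = [], []
        for dz in range(2):
            for dy in range(2):
                for dxo in range(2):
                    off = np.array([dxo, dy, dz])
                    cidx = base + off
                    w = np.prod(
                        np.where(off == 1, frac, 1.0 - frac), axis=-1
                    )
                    inb = np.all((cidx >= 0) & (cidx < shape), axis=-1)
                    cc = np.clip(cidx, 0, shape - 1)
                    isfluid = mask[cc[..., 0], cc[..., 1], cc[..., 2]] & inb
                    w = np.where(isfluid, w, 0.0)
                    corners.append(cc)
                    weights.append(w)
        self._corners = corners
        W = np.stack(weights)
        total = W.sum(axis=0)
        self.support = total > 1e-9
        total = np.where(self.support, total, 1.0)
        self._weights = W / total

    def _interp(self, field3d: np.ndarray) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        for cc, w in zip(self._corners, self._weights):
            vals = field3d[cc[..., 0], cc[..., 1], cc[..., 2]]
            out += w * np.nan_to_num(vals)
        return np.where(self.support, out, np.nan)

    def sample_scalar(self, field3d: np.ndarray) -> np.ndarray:
        return self._interp(field3d)

    def sample_normal_velocity(self, vel3d: np.ndarray) -> np.ndarray:
        """Component of a (3, nx, ny, nz) velocity field along the normal."""
        n = self.plane.normal
        return sum(n[a] * self._interp(vel3d[a]) for a in range(3))


@dataclass
class PlaneProfile:
    """Time series of the normal velocity component on a plane grid [m/s]."""

    plane: PlaneSpec
    times: np.ndarray  # (nt,) [s]
    values: np.ndarray  # (nt, na, nb); NaN marks non-fluid positions

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.times):
            raise ValueError("one 2-D frame per time stamp required")


def sample_plane(snapshots, plane: PlaneSpec, geometry: VesselGeometry) -> PlaneProfile:
    """Build a PlaneProfile from (time, velocity_field) snapshots.

    ``snapshots`` is an iterable of (t [s], (3, nx, ny, nz) field [m/s]).
    """
    sampler = PlaneSampler(geometry, plane)
    times, frames = [], []
    for t, field3d in snapshots:
        times.append(t)
        frames.append(sampler.sample_normal_velocity(field3d))
    return PlaneProfile(plane=plane, times=np.array(times), values=np.stack(frames))


def vmax_of_profile(profile: PlaneProfile, warmup: float = 0.0) -> float:
    """Maximum |normal velocity| over plane and time, excluding warm-up."""
    keep = profile.times >= warmup
    if not keep.any():
        raise ValueError("all samples fall within the warm-up window")
    vals = np.abs(profile.values[keep])
    if np.all(np.isnan(vals)):
        raise ValueError("profile contains no fluid samples")
    return float(np.nanmax(vals))


def _round_half_away(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def relative_difference(vmax_sim: float, vmax_tcd: float) -> float:
    """d_r = 100 (v_sim - v_TCD) / v_TCD, rounded half-away-from-zero to
    one decimal (the convention of clinical comparison tables)."""
    if vmax_tcd <= 0:
        raise ZeroDivisionError("reference velocity must be positive")
    return _round_half_away(100.0 * (vmax_sim - vmax_tcd) / vmax_tcd, 1)


def rescale_extracted(velocities, s: float):
    """Undo velocity scaling: multiply extracted velocities by 1/s.

    A run at 50% inflow velocity is rescaled by 2, at 25% by 4.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError("velocity scaling factor must lie in (0, 1]")
    return np.asarray(velocities) / s


@dataclass
class ComparisonRecord:
    """One row of the validation table: measured vs simulated peak velocity."""

    plane_label: str
    vmax_tcd: float
    vmax_sim: float
    rheology: str
    velocity_scaling: float = 1.0
    voxel_size: float = None
    dr: float = field(init=False)

    def __post_init__(self):
        self.dr = relative_difference(self.vmax_sim, self.vmax_tcd)


def wall_shear_stress(engine) -> tuple[np.ndarray, np.ndarray]:
    """WSS [Pa] at wall-adjacent fluid sites of the engine's current state.

    Returns (positions (n, 3) [m], stress (n,)); the stress is
    eta(gamma_dot) * gamma_dot with the local non-equilibrium shear-rate
    estimator, so Newtonian and Carreau-Yasuda runs use the same machinery.
    """
    gdot = engine.shear_rate_field()
    wall_sites = np.unique(np.concatenate([g.sites for g in engine.wall_groups]))
    g = gdot[wall_sites]
    eta = engine.rheology.viscosity(g)
    positions = engine.geometry.voxel_centers(engine.fluid_idx[wall_sites])
    return positions, np.asarray(eta) * g


def differential_pressure(density_snapshots, sampler: PlaneSampler,
                          unit: UnitSystem):
    """(min, mean, max) differential pressure [Pa] on a plane over time.

    For each snapshot (t, lattice density field), the pressure relative to
    the ideal-gas pressure at the instantaneous domain-average density is
    p = cs^2 (rho - rho_bar) in lattice units, converted to Pa.
    """
    p_scale = unit.to_physical(1.0, "pressure") / 3.0  # cs_lat^2 = 1/3
    times, mins, means, maxs = [], [], [], []
    for t, rho_field in density_snapshots:
        rho_bar = np.nanmean(rho_field)
        p = sampler.sample_scalar(rho_field - rho_bar) * p_scale
        times.append(t)
        mins.append(np.nanmin(p))
        means.append(np.nanmean(p))
        maxs.append(np.nanmax(p))
    return (np.array(times), np.array(mins), np.array(means), np.array(maxs))


@dataclass
class DimensionlessSummary:
    """Reynolds, Womersley and Mach numbers of a flow configuration."""

    U: float  # peak velocity [m/s]
    D: float  # characteristic diameter [m]
    nu: float  # kinematic viscosity [m^2/s]
    omega: float  # angular frequency of the cardiac cycle [rad/s]
    Re: float = field(init=False)
    alpha: float = field(init=False)
    Ma: float | None = None

    def __post_init__(self):
        if min(self.U, self.D, self.nu, self.omega) <= 0:
            raise ValueError("all inputs must be positive")
        self.Re = self.U * self.D / self.nu
        self.alpha = math.sqrt(self.omega * self.D**2 / self.nu)


def dimensionless_numbers(
    U: float, D: float, nu: float, omega: float, unit: UnitSystem | None = None
) -> DimensionlessSummary:
    """Re = U D / nu, alpha = (omega D^2 / nu)^(1/2), Ma = U / c_s."""
    summary = DimensionlessSummary(U=U, D=D, nu=nu, omega=omega)
    if unit is not None:
        summary.Ma = U / speed_of_sound(unit)
    return summary


@dataclass
class ScalingReport:
    """Consequences of running at reduced velocity U' = s U.

    At fixed geometry (D' = D), cardiac frequency (omega' = omega) and
    fluid (nu' = nu), the Womersley number is preserved but the Reynolds
    number drops to s Re — the flow regime changes, and the scaling
    identity s = nu' Re' D / (nu Re D') = alpha^2 omega' D' Re' /
    (alpha'^2 omega D Re) holds trivially on the reported quantities.
    """

    s: float
    Re: float
    Re_prime: float
    alpha: float
    alpha_prime: float
    Ma_prime: float
    tau_required: float
    feasible: bool
    regime_change: bool
    identity_ok: bool


def scaling_feasibility(
    summary: DimensionlessSummary, dx: float, dt: float, s: float = 1.0,
    rho_ref: float = 1000.0,
) -> ScalingReport:
    """Report the reduced-velocity run implied by scaling factor s.

    The required relaxation parameter follows the consistent
    tau - 1/2 = sqrt(3) (D / dx) (Ma' / Re') chain of the nu / c_s
    relations; tau <= 0.5 flags infeasibility.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError("velocity scaling factor must lie in (0, 1]")
    unit = UnitSystem(dx=dx, dt=dt, rho_ref=rho_ref)
    cs = speed_of_sound(unit)
    Re_prime = s * summary.Re
    alpha_prime = summary.alpha  # omega, D, nu all fixed
    Ma_prime = s * summary.U / cs
    tau = 0.5 + math.sqrt(3.0) * (summary.D / dx) * (Ma_prime / Re_prime)
    lhs = s
    rhs = (summary.nu * Re_prime * summary.D) / (summary.nu * summary.Re * summary.D)
    rhs2 = (summary.alpha**2 * summary.omega * summary.D * Re_prime) / (
        alpha_prime**2 * summary.omega * summary.D * summary.Re
    )
    identity_ok = abs(lhs - rhs) < 1e-12 and abs(lhs - rhs2) < 1e-12
    return ScalingReport(
        s=s,
        Re=summary.Re,
        Re_prime=Re_prime,
        alpha=summary.alpha,
        alpha_prime=alpha_prime,
        Ma_prime=Ma_prime,
        tau_required=tau,
        feasible=tau > 0.5,
        regime_change=abs(Re_prime - summary.Re) > 1e-12,
        identity_ok=identity_ok,
    )


def step_count(total_time: float, unit: UnitSystem) -> int:
    """Number of lattice steps spanning ``total_time`` seconds."""
    return int(round(total_time / unit.dt))
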