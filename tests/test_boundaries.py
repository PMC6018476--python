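"""Wall, inlet and outlet boundary treatments."""

import numpy as np
import pytest

from hemolat.boundaries import InletSpec, WallLinkGroup, bouzidi_wall_update, \
    ladd_inlet_update, parabolic_profile, warmup_ramp
from hemolat.engine import LBMEngine
from hemolat.geometry import make_straight_tube
from hemolat.lattice import _OPP
from hemolat.rheology import RheologySpec
from hemolat.units import UnitSystem
from hemolat.waveform import VelocityTrace


def test_warmup_ramp_endpoints_and_midpoint():
    assert warmup_ramp(0.0, 1.0) == 0.0
    assert warmup_ramp(1.0, 1.0) == 1.0
    assert warmup_ramp(2.5, 1.0) == 1.0
    assert warmup_ramp(0.5, 1.0) == pytest.approx(0.5)  # half-cosine midpoint
    assert warmup_ramp(0.3, 0.0) == 1.0  # no warm-up configured
    with pytest.raises(ValueError):
        warmup_ramp(-0.1, 1.0)


def test_warmup_ramp_monotone_and_smooth():
    t = np.linspace(0, 1, 200)
    vals = np.array([warmup_ramp(x, 1.0) for x in t])
    assert np.all(np.diff(vals) >= 0)
    # C1 at the start: initial slope vanishes
    assert vals[1] - vals[0] < 1e-3


def _dummy_inlet(d):
    return InletSpec(
        plane=None, trace=None, site_ids=np.arange(len(d)),
        profile_map=np.asarray(d, float), center_site=int(np.argmax(d)),
    )


def test_parabolic_profile_values():
    """u(d) = u_c (2d - d^2): 0 at the wall, u_c at the center,
    0.75 u_c at d = 1/2."""
    inlet = _dummy_inlet([0.0, 0.5, 1.0])
    speeds = parabolic_profile(inlet, 1.50)
    assert speeds == pytest.approx([0.0, 1.125, 1.50])


def test_bouzidi_halfway_reduces_to_bounce_back():
    """At q = 1/2 both interpolation branches equal simple bounce-back."""
    rng = np.random.default_rng(1)
    f_post = rng.random((19, 4)) + 0.5
    for q in (0.5 - 1e-9, 0.5, 0.5 + 1e-9):
        group = WallLinkGroup(
            direction=3, sites=np.array([1]), q=np.array([q]),
            upstream=np.array([0]),
        )
        f_new = np.zeros_like(f_post)
        bouzidi_wall_update(f_new, f_post, [group])
        assert f_new[_OPP[3], 1] == pytest.approx(f_post[3, 1], rel=1e-7)


def test_ladd_zero_velocity_is_pure_bounce_back():
    rng = np.random.default_rng(2)
    f_post = rng.random((19, 3)) + 0.5
    inlet = _dummy_inlet([1.0, 1.0, 1.0])
    inlet.link_dirs = np.array([5, 6])
    inlet.link_sites = np.array([0, 2])
    f_new = np.zeros_like(f_post)
    ladd_inlet_update(f_new, f_post, inlet, np.zeros((3, 3)))
    assert f_new[_OPP[5], 0] == f_post[5, 0]
    assert f_new[_OPP[6], 2] == f_post[6, 2]


def test_rest_state_is_fixed_point_with_all_boundaries():
    """A resting fluid with rho = rho0, zero-velocity inlet and open
    outlet stays at rest."""
    unit = UnitSystem(dx=1e-4, dt=1e-4, rho_ref=1000.0)
    geom = make_straight_tube(1.0e-3, 2.0e-3, unit)
    eng = LBMEngine(geom, RheologySpec.newtonian(eta=0.004))
    still = VelocityTrace(times=np.array([0.0, 1.0]),
                          velocities=np.zeros(2))
    eng.add_inlet(geom.inlet_planes[0], still)
    eng.add_outlet(geom.outlet_planes[0])
    eng.run(20)
    eng.refresh_moments()
    assert np.abs(eng.state.velocity).max() < 1e-13
    assert np.abs(eng.state.density - 1.0).max() < 1e-13


def test_poiseuille_centerline_accuracy(poiseuille24):
    """Steady tube with Ladd inlet, Bouzidi walls and Nash outlet
    reproduces the analytic Poiseuille centerline within 2%."""
    assert poiseuille24["centerline_error"] < 0.02
    assert poiseuille24["max_over_mean"] == pytest.approx(2.0, rel=0.03)


def test_poiseuille_inlet_dirichlet_fidelity(poiseuille24):
    """Measured inlet-plane velocities track the imposed profile within
    2% of the center speed away from the wall ring."""
    eng = poiseuille24["engine"]
    geom = poiseuille24["geometry"]
    inlet = eng.inlets[0]
    eng.refresh_moments()
    measured = eng.state.velocity[2, inlet.site_ids]
    target = geom.unit.to_lattice(inlet.target_speeds(eng.time), "velocity")
    core = inlet.profile_map > 0.25  # away from the wall ring
    err = np.abs(measured - target)[core].max() / target.max()
    assert err < 0.02


def test_outlet_in_plane_velocity_negligible(poiseuille24):
    """The mixed Dirichlet-Neumann outlet drives the in-plane velocity
    below 1e-3 of the axial speed in the core of the outlet plane (the
    wall ring retains a larger voxelization-induced secondary flow)."""
    eng = poiseuille24["engine"]
    geom = poiseuille24["geometry"]
    outlet = eng.outlets[0]
    eng.refresh_moments()
    u = eng.state.velocity[:, outlet.site_ids]
    n = outlet.plane.normal
    u_n = n @ u
    u_p = np.linalg.norm(u - np.outer(n, u_n), axis=0)
    centers = geom.voxel_centers(eng.fluid_idx[outlet.site_ids])
    r = np.linalg.norm(centers[:, :2], axis=1)
    core = r < 0.5 * 1.2e-3
    assert (u_p[core] / np.abs(u_n[core])).max() < 1e-3
    assert u_p.max() / np.abs(u_n).max() < 2e-2


def test_outlet_density_pinned_at_rho0(poiseuille24):
    eng = poiseuille24["engine"]
    outlet = eng.outlets[0]
    eng.refresh_moments()
    rho = eng.state.density[outlet.site_ids]
    assert np.abs(rho - eng.rho0).max() < 1e-12


def test_bouzidi_grid_convergence(poiseuille_refined_pair):
    """The L2 velocity error against the analytic parabola decreases
    faster than first order when dx is halved (diffusive scaling)."""
    coarse, fine = poiseuille_refined_pair
    order = np.log2(coarse["l2_error_vs_imposed"] / fine["l2_error_vs_imposed"])
    assert order > 1.0


def test_womersley_profile_accuracy(womersley_result):
    """Oscillatory inlet at alpha = 3 reproduces the analytic Womersley
    (Bessel-function) velocity profile within 5% L2 at mid-tube."""
    assert womersley_result["alpha"] == pytest.approx(3.0)
    assert womersley_result["l2_error"] < 0.05
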