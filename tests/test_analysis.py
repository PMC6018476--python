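"""Plane extraction, comparison statistics, WSS, pressure and the
dimensionless-number calculators."""

import numpy as np
import pytest

from hemolat.analysis import (
    ComparisonRecord,
    PlaneProfile,
    PlaneSampler,
    differential_pressure,
    dimensionless_numbers,
    relative_difference,
    rescale_extracted,
    sample_plane,
    scaling_feasibility,
    step_count,
    vmax_of_profile,
    wall_shear_stress,
)
from hemolat.geometry import define_measurement_plane, make_straight_tube
from hemolat.units import UnitSystem

UNIT = UnitSystem(dx=1e-4, dt=1e-5, rho_ref=1000.0)


@pytest.fixture(scope="module")
def tube():
    return make_straight_tube(1.6e-3, 3.2e-3, UNIT)


def _uniform_field(geometry, u_vec):
    shape = geometry.fluid_mask.shape
    field = np.full((3,) + shape, np.nan)
    for a in range(3):
        field[a][geometry.fluid_mask] = u_vec[a]
    return field


def test_sample_plane_uniform_flow(tube):
    """Uniform flow along the normal samples to a constant profile."""
    plane = define_measurement_plane(tube, [0, 0, 1.6e-3], [0, 0, 1], "mid")
    field = _uniform_field(tube, [0.0, 0.0, 0.8])
    prof = sample_plane([(0.0, field)], plane, tube)
    vals = prof.values[0]
    assert np.nanmax(vals) == pytest.approx(0.8, rel=1e-9)
    assert np.nanmin(vals) == pytest.approx(0.8, rel=1e-9)
    assert np.isnan(vals).any()  # non-fluid positions flagged, not zeroed


def test_sample_plane_tilted_reports_normal_component(tube):
    """A plane tilted 60 degrees from the flow reports the cosine-reduced
    normal component."""
    n = np.array([np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)])
    plane = define_measurement_plane(tube, [0, 0, 1.6e-3], n, "tilted")
    field = _uniform_field(tube, [0.0, 0.0, 0.8])
    prof = sample_plane([(0.0, field)], plane, tube)
    assert np.nanmax(np.abs(prof.values)) == pytest.approx(
        0.8 * np.cos(np.pi / 3), rel=1e-6
    )


def test_poiseuille_plane_profile_parabolic(poiseuille24):
    """Cross-plane sampling of steady pipe flow: max/mean ratio within 3%
    of the Poiseuille value 2."""
    eng = poiseuille24["engine"]
    geom = poiseuille24["geometry"]
    plane = define_measurement_plane(geom, [0, 0, 2.4e-3], [0, 0, 1], "cross")
    prof = sample_plane([(0.0, eng.velocity_field())], plane, geom)
    vals = prof.values[0]
    finite = np.isfinite(vals) & (np.abs(vals) > 0)
    ratio = np.nanmax(vals) / vals[finite].mean()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_vmax_warmup_exclusion():
    plane_values = np.ones((3, 2, 2))
    plane_values[0] *= 5.0  # a warm-up transient spike
    prof = PlaneProfile.__new__(PlaneProfile)
    prof.times = np.array([0.1, 1.1, 2.1])
    prof.values = plane_values
    prof.plane = None
    assert vmax_of_profile(prof, warmup=1.0) == 1.0
    assert vmax_of_profile(prof, warmup=0.0) == 5.0
    with pytest.raises(ValueError, match="warm-up"):
        vmax_of_profile(prof, warmup=10.0)


@pytest.mark.parametrize("pair,expected", [
    ((1.32, 1.43), -7.7),
    ((1.50, 1.61), -6.8),
    ((1.51, 1.61), -6.2),
    ((1.27, 1.32), -3.8),
    ((1.37, 1.26), +8.7),
    ((1.0, 1.0), 0.0),
])
def test_relative_difference_examples(pair, expected):
    assert relative_difference(*pair) == expected


def test_relative_difference_rejects_zero_reference():
    with pytest.raises(ZeroDivisionError):
        relative_difference(1.0, 0.0)


def test_comparison_record_invariant():
    rec = ComparisonRecord(plane_label="54 mm", vmax_tcd=1.61, vmax_sim=1.50,
                           rheology="newtonian")
    assert rec.dr == -6.8


@pytest.mark.parametrize("s,value,expected", [
    (0.5, 0.68, 1.36),
    (0.25, 0.305, 1.22),
    (1.0, 0.68, 0.68),
])
def test_rescale_extracted(s, value, expected):
    assert rescale_extracted(value, s) == pytest.approx(expected)


def test_rescale_guard():
    with pytest.raises(ValueError):
        rescale_extracted(1.0, 0.0)
    with pytest.raises(ValueError):
        rescale_extracted(1.0, 2.0)


def test_wall_shear_stress_poiseuille(poiseuille24):
    """Peak WSS on the mid-tube wall ring matches the Poiseuille value
    2 eta u_max / R within 5%."""
    eng = poiseuille24["engine"]
    geom = poiseuille24["geometry"]
    unit = geom.unit
    positions, wss = wall_shear_stress(eng)
    # restrict to the mid-tube region, away from inlet/outlet slices
    zmid = np.median(positions[:, 2])
    sel = np.abs(positions[:, 2] - zmid) < 5 * unit.dx
    eng.refresh_moments()
    u_max = np.nanmax(eng.state.velocity[2]) * unit.dx / unit.dt
    expected = 2.0 * eng.rheology.eta * u_max / 1.2e-3
    assert wss[sel].max() == pytest.approx(expected, rel=0.05)


def test_wall_shear_stress_zero_at_rest(tube):
    from hemolat.engine import LBMEngine
    from hemolat.rheology import RheologySpec

    eng = LBMEngine(tube, RheologySpec.newtonian())
    _, wss = wall_shear_stress(eng)
    assert np.abs(wss).max() < 1e-12


def test_differential_pressure_uniform_and_ordering(tube):
    plane = define_measurement_plane(tube, [0, 0, 1.6e-3], [0, 0, 1], "dp")
    sampler = PlaneSampler(tube, plane)
    shape = tube.fluid_mask.shape
    uniform = np.where(tube.fluid_mask, 1.0, np.nan)
    t, pmin, pmean, pmax = differential_pressure(
        [(0.0, uniform)], sampler, UNIT
    )
    assert pmin[0] == pytest.approx(0.0, abs=1e-12)
    assert pmax[0] == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(0)
    noisy = np.where(tube.fluid_mask, 1.0 + 0.01 * rng.random(shape), np.nan)
    t, pmin, pmean, pmax = differential_pressure([(0.0, noisy)], sampler, UNIT)
    assert pmin[0] <= pmean[0] <= pmax[0]


def test_differential_pressure_steady_poiseuille_constant(poiseuille24):
    """In a converged steady run the outlet-plane differential pressure
    is constant in time."""
    eng = poiseuille24["engine"]
    geom = poiseuille24["geometry"]
    plane = geom.outlet_planes[0]
    sampler = PlaneSampler(geom, plane)
    snaps = []
    for _ in range(3):
        eng.run(50)
        snaps.append((eng.time, eng.density_field()))
    t, pmin, pmean, pmax = differential_pressure(snaps, sampler, geom.unit)
    assert np.ptp(pmean) <= 0.02 * max(abs(pmean).max(), 1e-12) + 1e-9


def test_dimensionless_numbers_mca():
    """Re = 966 for U = 1.61 m/s, D = 2.4 mm, nu = 4e-6 m^2/s; halving U
    halves Re; alpha ~ 3.18 at the measured inflow cardiac frequency."""
    s = dimensionless_numbers(1.61, 2.4e-3, 4.0e-6, 2 * np.pi / 0.894)
    assert s.Re == pytest.approx(966, abs=1.0)
    assert s.alpha == pytest.approx(3.18, abs=0.01)
    s_half = dimensionless_numbers(1.61 / 2, 2.4e-3, 4.0e-6, 2 * np.pi / 0.894)
    assert s_half.Re == pytest.approx(483, abs=0.5)


def test_scaling_feasibility_reports():
    base = dimensionless_numbers(1.61, 2.4e-3, 4.0e-6, 2 * np.pi / 0.894)
    rep = scaling_feasibility(base, dx=1e-5, dt=0.28e-6, s=0.5)
    assert rep.Re_prime == pytest.approx(483, abs=0.5)
    assert rep.alpha_prime == base.alpha  # Womersley number preserved
    assert rep.regime_change and rep.identity_ok and rep.feasible
    assert rep.tau_required > 0.5
    rep25 = scaling_feasibility(base, dx=1e-5, dt=0.28e-6, s=0.25)
    assert rep25.Re_prime == pytest.approx(241.5, abs=0.5)
    ident = scaling_feasibility(base, dx=1e-5, dt=0.28e-6, s=1.0)
    assert ident.Re_prime == base.Re and not ident.regime_change


def test_step_count_production_run():
    """One second of warm-up plus five measured seconds at dt = 0.28 us
    is 21.43 million steps."""
    unit = UnitSystem(dx=1e-5, dt=0.28e-6, rho_ref=1000.0)
    n = step_count(1.0 + 5.0, unit)
    assert n / 1e6 == pytest.approx(21.43, abs=0.005)
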