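"""Vessel synthesis, voxelization and wall-link fractions."""

import numpy as np
import pytest

from hemolat.geometry import (
    GeometryError,
    LINK_WALL,
    PlaneSpec,
    ResolutionError,
    define_measurement_plane,
    inlet_profile_map,
    make_bifurcation,
    make_curved_tube,
    make_straight_tube,
)
from hemolat.lattice import D3Q19
from hemolat.units import UnitSystem

UNIT = UnitSystem(dx=1e-4, dt=1e-5, rho_ref=1000.0)


@pytest.fixture(scope="module")
def tube24():
    return make_straight_tube(2.4e-3, 12e-3, UNIT)


def test_straight_tube_site_count(tube24):
    """Fluid site count matches pi R^2 L / dx^3 within 5%."""
    expected = np.pi * 1.2e-3**2 * 12e-3 / UNIT.dx**3
    assert abs(tube24.n_fluid - expected) / expected < 0.05


def test_straight_tube_resolution_guard():
    with pytest.raises(ResolutionError):
        make_straight_tube(4 * UNIT.dx, 1e-3, UNIT)


def test_wall_fractions_in_range(tube24):
    q = tube24.link_q
    assert q.size > 0
    assert np.all((q > 0.0) & (q <= 1.0))


def test_wall_fractions_match_circle_intersections(tube24):
    """q on wall-cut links reproduces the exact quadratic-formula
    circle intersection to 1e-6 of a link length."""
    wall = tube24.link_kind == LINK_WALL
    sites = tube24.link_site[wall]
    dirs = tube24.link_dir[wall]
    qs = tube24.link_q[wall]
    ijk = np.stack(np.unravel_index(sites, tube24.fluid_mask.shape), axis=1)
    p = tube24.voxel_centers(ijk)[:, :2]  # tube axis along z through (0, 0)
    c = D3Q19.velocities[dirs][:, :2] * UNIT.dx
    R = 1.2e-3
    # |p + q c|^2 = R^2  ->  aa q^2 + 2 bb q + cc = 0
    aa = (c**2).sum(axis=1)
    bb = (p * c).sum(axis=1)
    cc = (p**2).sum(axis=1) - R**2
    axial = aa < 1e-30  # purely axial links never cut the cylinder wall
    assert not axial.any()
    q_exact = (-bb + np.sqrt(bb**2 - aa * cc)) / aa
    assert np.allclose(qs, q_exact, atol=1e-6)


def test_volume_convergence_under_refinement():
    """Voxelized volume error shrinks when dx is halved."""
    analytic = np.pi * 1.2e-3**2 * 6e-3

    def vol_err(dx):
        unit = UnitSystem(dx=dx, dt=1e-5)
        g = make_straight_tube(2.4e-3, 6e-3, unit)
        return abs(g.fluid_volume() - analytic) / analytic

    assert vol_err(5e-5) < vol_err(1e-4)


def test_planar_wall_halfway_q():
    """A flat cap halfway along an axial link gives q = 0.5 exactly:
    the inlet cap sits on a voxel face, half a link from the first fluid
    site center."""
    g = make_straight_tube(2.4e-3, 4e-3, UNIT)
    inlet_idx = g.planes.index(g.inlet_planes[0])
    sel = g.link_plane == inlet_idx
    axial = D3Q19.velocities[g.link_dir[sel]][:, 2] != 0
    q_axial = g.link_q[sel][axial & (np.abs(
        D3Q19.velocities[g.link_dir[sel]][:, :2]).sum(axis=1) == 0)]
    assert q_axial.size > 0
    assert np.allclose(q_axial, 0.5, atol=1e-9)


def test_curved_tube_arc_length_and_degenerate_bend():
    g = make_curved_tube(2.4e-3, 6e-3, 90.0, UNIT)
    assert g.lumen.arc_length == pytest.approx(np.pi / 2 * 6e-3)
    # zero bend degenerates to a straight tube of the same total length
    g0 = make_curved_tube(2.4e-3, 6e-3, 0.0, UNIT, ext_length=3e-3)
    straight = make_straight_tube(2.4e-3, 6e-3, UNIT)
    assert abs(g0.n_fluid - straight.n_fluid) / straight.n_fluid < 0.02


def test_curved_tube_guard():
    with pytest.raises(GeometryError):
        make_curved_tube(2.4e-3, 2e-3, 90.0, UNIT)


def test_bifurcation_planes_and_guards():
    g = make_bifurcation(2.4e-3, (1.8e-3, 1.8e-3), 60.0, UNIT)
    assert len(g.inlet_planes) == 1
    assert len(g.outlet_planes) == 2
    with pytest.raises(GeometryError):
        make_bifurcation(2.4e-3, (0.0, 1.8e-3), 60.0, UNIT)
    with pytest.raises(GeometryError):
        make_bifurcation(2.4e-3, (3.0e-3, 1.8e-3), 60.0, UNIT)
    with pytest.raises(GeometryError):  # overlapping daughters
        make_bifurcation(2.4e-3, (1.8e-3, 1.8e-3), 2.0, UNIT)


def test_symmetric_bifurcation_splits_flux_evenly(bifurcation_symmetric_fluxes):
    """A symmetric Y with equal daughters splits steady flow 50/50
    within 2%."""
    _, (f1, f2) = bifurcation_symmetric_fluxes
    assert f1 > 0 and f2 > 0
    assert abs(f1 - f2) / (f1 + f2) < 0.02


def test_unequal_bifurcation_flux_ordering(bifurcation_unequal_fluxes):
    """The narrower daughter carries a nonzero minority of the flux
    (hydraulic resistance grows steeply with decreasing diameter)."""
    _, (f_wide, f_narrow) = bifurcation_unequal_fluxes
    assert f_narrow > 0
    assert f_narrow < f_wide
    assert f_narrow / (f_wide + f_narrow) < 0.45


def test_bend_skews_downstream_velocity_maximum(inertial_rescaling):
    """Steady high-Re flow through a bend shifts the velocity maximum
    away from the centerline of the downstream plane."""
    field = inertial_rescaling["plane_full"]
    finite = np.isfinite(field)
    ii, jj = np.nonzero(finite)
    center = np.array([ii.mean(), jj.mean()])
    kmax = np.unravel_index(np.nanargmax(np.abs(field)), field.shape)
    offset = np.linalg.norm(np.array(kmax, dtype=float) - center)
    lumen_radius_px = np.sqrt(finite.sum() / np.pi)
    assert offset / lumen_radius_px > 0.15


def test_measurement_plane_registry(tube24):
    plane = define_measurement_plane(
        tube24, [0.0, 0.0, 6e-3], [0.0, 0.0, 1.0], "49 mm"
    )
    assert tube24.plane_by_label("49 mm") is plane
    assert plane.role == "measurement"
    with pytest.raises(KeyError):
        tube24.plane_by_label("unknown")


def test_measurement_plane_outside_lumen_rejected(tube24):
    with pytest.raises(GeometryError, match="outside"):
        define_measurement_plane(
            tube24, [5e-3, 5e-3, 6e-3], [0.0, 0.0, 1.0], "bad"
        )


def test_non_unit_normal_normalized_with_warning():
    """A Table-2-style normal with unit norm passes silently; a non-unit
    normal is normalized with a warning."""
    loc = np.zeros(3)
    p = PlaneSpec(loc, np.array([0.9474, 0.2650, 0.1796]), "measurement", "p1")
    assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)
    with pytest.warns(UserWarning, match="normalizing"):
        p2 = PlaneSpec(loc, np.array([0.0, 0.0, 2.0]), "measurement", "p2")
    assert np.linalg.norm(p2.normal) == pytest.approx(1.0, abs=1e-12)


def test_inlet_profile_map_endpoints(tube24):
    ijk, d, center = inlet_profile_map(tube24, tube24.inlet_planes[0])
    assert d.max() <= 1.0 and d.min() >= 0.0
    assert d[center] == d.max()
    centers = tube24.voxel_centers(ijk)
    r = np.linalg.norm(centers[:, :2], axis=1)
    # analytic map: d = 1 - r/R
    assert np.allclose(d, 1.0 - r / 1.2e-3, atol=1e-9)


def test_discrete_profile_map_agrees_with_analytic_in_the_core():
    """The nearest-wall-site rule matches the analytic wall distance to
    O(dx) away from the wall ring."""
    g = make_straight_tube(3.2e-3, 4e-3, UNIT)
    plane = g.inlet_planes[0]
    ijk_a, d_a, _ = inlet_profile_map(g, plane, method="analytic")
    ijk_s, d_s, _ = inlet_profile_map(g, plane, method="sites")
    assert np.array_equal(ijk_a, ijk_s)
    core = d_a > 0.5
    assert np.max(np.abs(d_a[core] - d_s[core])) < 0.12
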