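"""Shared fixtures: the expensive solver runs are session-scoped so the
steady Poiseuille tube, the oscillatory Womersley tube and the curved-tube
rescaling pairs are each simulated once and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hemolat.benchmarks import (
    poiseuille_benchmark,
    rescaling_benchmark,
    rheology_sensitivity_benchmark,
    shear_wave_benchmark,
    womersley_benchmark,
)


@pytest.fixture(scope="session")
def poiseuille24():
    """Steady pipe flow, 24 voxels across the diameter, Re = 24."""
    return poiseuille_benchmark(n_diameter=24)


@pytest.fixture(scope="session")
def poiseuille_refined_pair():
    """Low-Re Poiseuille at 12 and 24 voxels/diameter under diffusive
    scaling (u_lat halved with dx), for grid-convergence checks."""
    coarse = poiseuille_benchmark(
        n_diameter=12, u_lat=0.05, reynolds=5.0, tube_length_d=4.0,
        max_steps=8000,
    )
    fine = poiseuille_benchmark(
        n_diameter=24, u_lat=0.025, reynolds=5.0, tube_length_d=4.0,
        max_steps=16000,
    )
    return coarse, fine


@pytest.fixture(scope="session")
def womersley_result():
    return womersley_benchmark()


@pytest.fixture(scope="session")
def shear_wave_results():
    return {
        "newtonian": shear_wave_benchmark("newtonian"),
        "carreau_yasuda": shear_wave_benchmark("carreau_yasuda"),
    }


@pytest.fixture(scope="session")
def stokes_rescaling():
    return rescaling_benchmark(
        reynolds=0.2, n_diameter=12, u_lat=0.02, n_steps=600, warmup_steps=100
    )


@pytest.fixture(scope="session")
def inertial_rescaling():
    return rescaling_benchmark()


@pytest.fixture(scope="session")
def rheology_sensitivity():
    return rheology_sensitivity_benchmark()


def _bifurcation_fluxes(daughter_diameters):
    """Steady low-Re flow through a Y-junction; returns outlet fluxes."""
    from hemolat.analysis import PlaneSampler
    from hemolat.engine import LBMEngine
    from hemolat.geometry import make_bifurcation
    from hemolat.rheology import RheologySpec
    from hemolat.units import UnitSystem
    from hemolat.waveform import VelocityTrace

    dx = 1e-4
    D = 1.6e-3
    U = 0.02
    reynolds = 20.0
    nu = U * D / reynolds
    dt = 0.05 * dx / U
    unit = UnitSystem(dx=dx, dt=dt, rho_ref=1000.0)
    geom = make_bifurcation(D, daughter_diameters, 60.0, unit)
    engine = LBMEngine(geom, RheologySpec.newtonian(eta=nu * unit.rho_ref))
    trace = VelocityTrace(times=np.array([0.0, 1e9]),
                          velocities=np.array([U, U]))
    engine.add_inlet(geom.inlet_planes[0], trace, warmup_duration=200 * dt)
    samplers = []
    for plane in geom.outlet_planes:
        engine.add_outlet(plane)
        samplers.append(PlaneSampler(geom, plane))
    engine.run(2500)
    field = engine.velocity_field()
    fluxes = [np.nansum(s.sample_normal_velocity(field)) * dx**2
              for s in samplers]
    return geom, fluxes


@pytest.fixture(scope="session")
def bifurcation_symmetric_fluxes():
    return _bifurcation_fluxes((1.2e-3, 1.2e-3))


@pytest.fixture(scope="session")
def bifurcation_unequal_fluxes():
    return _bifurcation_fluxes((1.2e-3, 0.8e-3))
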