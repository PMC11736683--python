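"""Shared fixtures: surrogate trajectories sized so that statistical
tolerances sit at roughly three standard errors.

All generators are seeded, so every fixture is deterministic; the
session scope means each simulation runs once for the whole suite.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import permeant as pm

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

KT310 = pm.kBT(310.0)


@pytest.fixture(scope="session")
def flat_traj():
    """Flat-profile 1D Brownian run: D = 0.5 Å²/ps, 80 Å periodic box."""
    spec = pm.PermeationSystemSpec(
        F=0.0, D=0.5, box_z=80.0, dt=0.5, n_steps=640_000,
        n_particles=10, seed=101,
    )
    return spec, pm.simulate_permeation_1d(spec)


@pytest.fixture(scope="session")
def barrier_traj():
    """5 kJ/mol Gaussian barrier (σ = 5 Å) at the membrane center, T = 310 K."""
    F, dF = pm.gaussian_profile([5.0], [0.0], [5.0])
    spec = pm.PermeationSystemSpec(
        F=F, dF=dF, D=0.5, box_z=80.0, dt=0.5, n_steps=300_000,
        n_particles=10, seed=21,
    )
    return spec, pm.simulate_permeation_1d(spec)


@pytest.fixture(scope="session")
def well_traj():
    """2 kBT-deep Gaussian well (σ = 6 Å) at the center; dt small enough
    that the Euler–Maruyama stationary law is Boltzmann to within the
    block errors."""
    F, dF = pm.gaussian_profile([-2 * KT310], [0.0], [6.0])
    spec = pm.PermeationSystemSpec(
        F=F, dF=dF, D=0.5, box_z=80.0, dt=0.2, n_steps=750_000,
        n_particles=8, seed=31,
    )
    return spec, pm.simulate_permeation_1d(spec)


@pytest.fixture(scope="session")
def free3d_traj():
    """Free 3D Brownian ensemble at the water-diffusivity scale."""
    return pm.simulate_free_3d(
        D=0.714, box=100.0, n_particles=10, dt=1.0, n_steps=100_000, seed=15
    )


@pytest.fixture(scope="session")
def square_well_traj():
    """Metropolis walk with one 3 kJ/mol spherical square well."""
    spec = pm.BindingSystemSpec(
        box=30.0, wells=[((0.0, 0.0, 0.0), 5.0, 3.0)], step_size=1.0,
        dt=20.0, n_steps=400_000, n_particles=8, seed=41,
    )
    return spec, pm.simulate_binding_3d(spec)
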