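"""Surrogate trajectory generators.

These generators produce trajectories with the exact statistical structure
the analysis stages assume, standing in for a molecular-dynamics engine:

* :func:`simulate_permeation_1d` — overdamped Langevin (Brownian) dynamics
  of independent permeants on a 1D free-energy profile F(z) with
  position-dependent diffusivity D(z), periodic in z.  The Itô convention
  with the spurious-drift term D′(z) is used, so the stationary law is the
  Boltzmann distribution ∝ exp(−F/kBT) regardless of D(z).
* :func:`simulate_binding_3d` — a Metropolis random walk in a periodic box
  containing spherical square wells of depth ε.  Metropolis dynamics handle
  the discontinuous potential exactly: the stationary in/out number-density
  ratio per well is exp(ε/kBT).  Kinetics (residence times) are only
  qualitatively diffusive; occupancy ratios are the quantitatively exact
  observable.
* :func:`simulate_free_3d` — free 3D Brownian motion in a periodic box.

All generators are seed-deterministic (one ``numpy.random.Generator`` per
spec, no global state) and return :class:`~permeant.trajectory.Trajectory`
objects carrying wrapped and unwrapped coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import DEFAULT_TEMPERATURE, kBT
from .errors import StabilityError, ValidationError
from .trajectory import Trajectory

__all__ = [
    "PermeationSystemSpec",
    "BindingSystemSpec",
    "simulate_permeation_1d",
    "simulate_binding_3d",
    "simulate_free_3d",
    "gaussian_profile",
    "tabulated_profile",
]


# ---------------------------------------------------------------------------
# Free-energy profile helpers
# ---------------------------------------------------------------------------

def gaussian_profile(heights, centers, sigmas):
    """Sum-of-Gaussians free energy: F(z) = Σ h_i exp(−(z−c_i)²/2σ_i²).

    Returns ``(F, dF)`` callables (kJ/mol, kJ/mol/Å).  Negative heights make
    wells, positive ones barriers.
    """
    heights = np.atleast_1d(np.asarray(heights, dtype=float))
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if not (len(heights) == len(centers) == len(sigmas)):
        raise ValidationError("heights, centers, sigmas must have equal length")
    if np.any(sigmas <= 0):
        raise ValidationError("sigmas must be positive")

    def F(z):
        z = np.asarray(z, dtype=float)
        val = np.zeros_like(z)
        for h, c, s in zip(heights, centers, sigmas):
            val = val + h * np.exp(-((z - c) ** 2) / (2 * s**2))
        return val

    def dF(z):
        z = np.asarray(z, dtype=float)
        val = np.zeros_like(z)
        for h, c, s in zip(heights, centers, sigmas):
            val = val + h * np.exp(-((z - c) ** 2) / (2 * s**2)) * (-(z - c) / s**2)
        return val

    return F, dF


def tabulated_profile(z_table, f_table, box_z):
    """Periodic cubic interpolation of a binned profile.

    Returns ``(F, dF)`` where dF is the analytic derivative of the cubic
    interpolant.  The table is extended periodically over ``box_z``.
    """
    z_table = np.asarray(z_table, dtype=float)
    f_table = np.asarray(f_table, dtype=float)
    order = np.argsort(z_table)
    z_table, f_table = z_table[order], f_table[order]
    # build one full period with matching endpoints
    z_ext = np.append(z_table, z_table[0] + box_z)
    f_ext = np.append(f_table, f_table[0])
    spline = CubicSpline(z_ext, f_ext, bc_type="periodic")
    z0, L = z_table[0], box_z
    dspline = spline.derivative()

    def F(z):
        return spline(np.mod(np.asarray(z, dtype=float) - z0, L) + z0)

    def dF(z):
        return dspline(np.mod(np.asarray(z, dtype=float) - z0, L) + z0)

    return F, dF


def _as_function_pair(f, df, box_z, name):
    """Normalize (callable|scalar|table, derivative|None) to callables."""
    if np.isscalar(f):
        const = float(f)
        return (lambda z: np.full_like(np.asarray(z, dtype=float), const),
                lambda z: np.zeros_like(np.asarray(z, dtype=float)))
    if callable(f):
        if df is not None:
            return f, df
        # derivative via periodic cubic interpolant on a dense grid
        grid = np.linspace(-box_z / 2, box_z / 2, 2049)
        return tabulated_profile(grid[:-1], np.asarray(f(grid[:-1]), dtype=float), box_z)
    raise ValidationError(f"{name} must be a scalar or callable")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class PermeationSystemSpec:
    """1D permeation surrogate: Brownian particles on F(z), D(z).

    ``F`` and ``D`` may be callables (with optional analytic derivatives
    ``dF``/``dD``) or constants; tables go through
    :func:`tabulated_profile` first.  The lateral box is 1 Å × 1 Å by
    convention so that area-normalized quantities are well-defined for 1D
    systems.
    """

    F: object = 0.0
    D: object = 0.5
    box_z: float = 80.0
    dt: float = 0.5
    n_steps: int = 10_000
    n_particles: int = 1
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    dF: object = None
    dD: object = None
    save_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.box_z <= 0:
            raise ValidationError("box_z must be positive")
        if self.n_steps < 0 or self.n_particles < 1 or self.save_every < 1:
            raise ValidationError("invalid step/particle/save counts")
        self._F, self._dF = _as_function_pair(self.F, self.dF, self.box_z, "F")
        self._D, self._dD = _as_function_pair(self.D, self.dD, self.box_z, "D")
        grid = np.linspace(-self.box_z / 2, self.box_z / 2, 4097)
        dvals = np.asarray(self._D(grid), dtype=float)
        if np.any(dvals <= 0):
            raise ValidationError("D(z) must be positive everywhere")
        fl, fr = float(self._F(-self.box_z / 2)), float(self._F(self.box_z / 2))
        if abs(fl - fr) > 1e-9:
            raise ValidationError(
                f"F must match at the periodic edges: F(-L/2)={fl}, F(+L/2)={fr}"
            )
        drift = np.abs(
            -dvals * np.asarray(self._dF(grid)) / kBT(self.temperature)
            + np.asarray(self._dD(grid))
        ) * self.dt
        if drift.max() > self.box_z / 4:
            raise StabilityError(
                f"dt={self.dt} ps gives a max single-step drift of "
                f"{drift.max():.3g} Å > box_z/4; reduce dt"
            )


@dataclass
class BindingSystemSpec:
    """3D Metropolis walk in a cubic box with spherical square wells.

    ``wells`` is a list of ``(center, radius, depth)`` with center an
    (x, y, z) triple in Å and depth ε ≥ 0 in kJ/mol (attractive).
    """

    box: float = 30.0
    wells: list = field(default_factory=list)
    step_size: float = 1.0
    dt: float = 20.0
    n_steps: int = 10_000
    n_particles: int = 1
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    D: float = 0.5  # nominal diffusivity, bookkeeping only
    save_every: int = 1

    def __post_init__(self):
        if self.box <= 0 or self.step_size <= 0 or self.dt <= 0:
            raise ValidationError("box, step_size and dt must be positive")
        if self.n_steps < 0 or self.n_particles < 1 or self.save_every < 1:
            raise ValidationError("invalid step/particle/save counts")
        centers = np.array([w[0] for w in self.wells], dtype=float).reshape(-1, 3)
        radii = np.array([w[1] for w in self.wells], dtype=float)
        depths = np.array([w[2] for w in self.wells], dtype=float)
        if np.any(radii <= 0):
            raise ValidationError("well radii must be positive")
        if np.any(depths < 0):
            raise ValidationError("well depths must be non-negative")
        for i in range(len(self.wells)):
            for j in range(i + 1, len(self.wells)):
                d = centers[i] - centers[j]
                d -= np.round(d / self.box) * self.box
                if np.linalg.norm(d) <= radii[i] + radii[j]:
                    raise ValidationError(f"wells {i} and {j} overlap")
        self._centers, self._radii, self._depths = centers, radii, depths


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _boltzmann_initial_z(spec, rng, n):
    """Draw initial z from exp(−F/kBT) by inverse-CDF on a fine grid."""
    grid = np.linspace(-spec.box_z / 2, spec.box_z / 2, 8193)
    w = np.exp(-np.asarray(spec._F(grid), dtype=float) / kBT(spec.temperature))
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, grid)


def simulate_permeation_1d(spec: PermeationSystemSpec) -> Trajectory:
    """Run overdamped Langevin dynamics on a 1D periodic free-energy profile.

    The Itô update is

        z ← z + [−D(z) F′(z)/kBT + D′(z)]·dt + √(2 D(z) dt)·𝒩(0,1)

    wrapped into (−box_z/2, box_z/2]; unwrapped coordinates are accumulated
    alongside.  Initial positions are drawn from the stationary Boltzmann
    law so histograms are equilibrium samples from the first frame.
    """
    rng = np.random.default_rng(spec.seed)
    kt = kBT(spec.temperature)
    n = spec.n_particles
    L = spec.box_z

    z = _boltzmann_initial_z(spec, rng, n)
    zu = z.copy()
    n_saved = spec.n_steps // spec.save_every + 1
    zs = np.empty((n_saved, n))
    zus = np.empty((n_saved, n))
    zs[0], zus[0] = z, zu
    k = 1
    for step in range(1, spec.n_steps + 1):
        D = np.asarray(spec._D(z), dtype=float)
        drift = (-D * np.asarray(spec._dF(z), dtype=float) / kt
                 + np.asarray(spec._dD(z), dtype=float)) * spec.dt
        noise = np.sqrt(2 * D * spec.dt) * rng.standard_normal(n)
        dz = drift + noise
        zu = zu + dz
        z = z + dz
        z -= np.round(z / L) * L
        if step % spec.save_every == 0:
            zs[k], zus[k] = z, zu
            k += 1

    times = spec.dt * spec.save_every * np.arange(n_saved)
    positions = np.zeros((n_saved, n, 3))
    positions[:, :, 2] = zs
    unwrapped = np.zeros((n_saved, n, 3))
    unwrapped[:, :, 2] = zus
    return Trajectory(
        times=times,
        positions=positions,
        box=np.array([1.0, 1.0, L]),
        labels=["permeant"] * n,
        unwrapped=unwrapped,
        periodic=(False, False, True),
    )


def _in_any_well(pos, spec):
    """Boolean mask: which particles are inside any well (minimum image)."""
    if len(spec.wells) == 0:
        return np.zeros(len(pos), dtype=bool)
    d = pos[:, None, :] - spec._centers[None, :, :]
    d -= np.round(d / spec.box) * spec.box
    dist = np.sqrt((d**2).sum(axis=2))
    return (dist <= spec._radii[None, :]).any(axis=1)


def _well_energy(pos, spec):
    """Potential energy per particle: −ε inside a well, 0 outside."""
    if len(spec.wells) == 0:
        return np.zeros(len(pos))
    d = pos[:, None, :] - spec._centers[None, :, :]
    d -= np.round(d / spec.box) * spec.box
    dist = np.sqrt((d**2).sum(axis=2))
    inside = dist <= spec._radii[None, :]
    # wells are non-overlapping: at most one well contributes
    return -(inside * spec._depths[None, :]).sum(axis=1)


def simulate_binding_3d(spec: BindingSystemSpec) -> Trajectory:
    """Metropolis random walk among spherical square wells.

    Isotropic Gaussian proposals of scale ``step_size``; acceptance
    min(1, exp(−ΔU/kBT)) with U = −ε inside a well and 0 outside.  The
    nominal time per step is ``dt`` for downstream time bookkeeping.
    """
    rng = np.random.default_rng(spec.seed)
    kt = kBT(spec.temperature)
    n, L = spec.n_particles, spec.box

    pos = rng.uniform(-L / 2, L / 2, size=(n, 3))
    unw = pos.copy()
    U = _well_energy(pos, spec)
    n_saved = spec.n_steps // spec.save_every + 1
    out = np.empty((n_saved, n, 3))
    out_u = np.empty((n_saved, n, 3))
    out[0], out_u[0] = pos, unw
    k = 1
    for step in range(1, spec.n_steps + 1):
        prop_step = spec.step_size * rng.standard_normal((n, 3))
        prop = pos + prop_step
        prop -= np.round(prop / L) * L
        U_new = _well_energy(prop, spec)
        accept = rng.uniform(size=n) < np.exp(-np.minimum((U_new - U) / kt, 700))
        pos = np.where(accept[:, None], prop, pos)
        unw = unw + np.where(accept[:, None], prop_step, 0.0)
        U = np.where(accept, U_new, U)
        if step % spec.save_every == 0:
            out[k], out_u[k] = pos, unw
            k += 1

    times = spec.dt * spec.save_every * np.arange(n_saved)
    return Trajectory(
        times=times,
        positions=out,
        box=np.array([L, L, L]),
        labels=["permeant"] * n,
        unwrapped=out_u,
    )


def simulate_free_3d(D, box, n_particles, dt, n_steps, seed) -> Trajectory:
    """Independent free Brownian particles in a periodic cubic box."""
    if D <= 0:
        raise ValidationError("D must be positive")
    if dt <= 0 or box <= 0:
        raise ValidationError("dt and box must be positive")
    if n_steps < 0 or n_particles < 1:
        raise ValidationError("invalid step/particle counts")
    rng = np.random.default_rng(seed)
    start = rng.uniform(-box / 2, box / 2, size=(1, n_particles, 3))
    steps = np.sqrt(2 * D * dt) * rng.standard_normal((n_steps, n_particles, 3))
    unwrapped = start + np.concatenate(
        [np.zeros((1, n_particles, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    wrapped = unwrapped - np.round(unwrapped / box) * box
    return Trajectory(
        times=dt * np.arange(n_steps + 1),
        positions=wrapped,
        box=np.array([box, box, box]),
        labels=["permeant"] * n_particles,
        unwrapped=unwrapped,
    )
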