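"""Counting-method membrane permeability and the ISD integral.

The counting method follows each permeant through an equilibrium
trajectory and counts complete membrane crossings between two dividing
surfaces at z = ±h/2, placed a fixed offset (default 8 Å) beyond the mean
|z| of the phosphate particles so the whole membrane slab is included.
The permeability is

    P = n_crossings / (2 · A · t_sim · c_w)

with A the mean lateral box area, t_sim the sampled time, and c_w the mean
permeant number density in the water phase (|z| > h/2).  The factor 2
accounts for both crossing directions being counted.  P is reported in
cm/s (1 Å/ps = 10⁴ cm/s).

The inhomogeneous solubility–diffusivity (ISD) relation

    1/P = ∫_{−h/2}^{+h/2} exp(F(z)/kBT) / D(z) dz

serves as the closed-form oracle on synthetic systems where F and D are
known inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .constants import ANGSTROM_PER_PS_TO_CM_PER_S, DEFAULT_TEMPERATURE, kBT
from .errors import GeometryError, ReferenceRegionError, ValidationError
from .trajectory import Trajectory

__all__ = [
    "MembraneGeometry",
    "CrossingEvent",
    "PermeabilityResult",
    "dividing_surfaces",
    "detect_crossings",
    "counting_permeability",
    "isd_permeability",
    "CountingPermeabilityModel",
]


@dataclass(frozen=True)
class MembraneGeometry:
    """Dividing surfaces at z = ±h/2 delimiting the membrane slab."""

    half_thickness: float
    phosphate_mean_abs_z: float = None
    offset: float = 8.0

    def __post_init__(self):
        if self.half_thickness <= 0:
            raise ValidationError("half thickness must be positive")
        if self.phosphate_mean_abs_z is not None:
            expected = self.phosphate_mean_abs_z + self.offset
            if abs(expected - self.half_thickness) > 1e-9:
                raise ValidationError(
                    "half_thickness must equal phosphate_mean_abs_z + offset"
                )

    @property
    def dividing_surfaces(self) -> tuple:
        return (-self.half_thickness, self.half_thickness)


@dataclass(frozen=True)
class CrossingEvent:
    """One complete water→membrane→water traversal of a single permeant."""

    particle: int
    t_entry: float
    t_exit: float
    direction: str  # "+z" | "-z"

    def __post_init__(self):
        if self.t_exit < self.t_entry:
            raise ValidationError("t_exit must be >= t_entry")
        if self.direction not in ("+z", "-z"):
            raise ValidationError("direction must be '+z' or '-z'")


@dataclass
class PermeabilityResult:
    """Counting-method permeability with Poisson error."""

    n_crossings: int
    events: list = field(default_factory=list)
    area: float = 1.0          # Å²
    sim_time: float = 0.0      # ps
    c_water: float = 0.0       # Å⁻³
    P: float = 0.0             # cm/s
    P_err: float = math.nan    # cm/s; NaN when n_crossings == 0
    half_thickness: float = math.nan

    def summary(self) -> str:
        err = f"{self.P_err:.4g}" if np.isfinite(self.P_err) else "undefined"
        lines = [
            "Counting-method permeability",
            "=" * 40,
            f"crossings: {self.n_crossings} "
            f"(+z: {sum(e.direction == '+z' for e in self.events)}, "
            f"-z: {sum(e.direction == '-z' for e in self.events)})",
            f"h/2: {self.half_thickness:.3f} Å   area: {self.area:.4g} Å²",
            f"sampled time: {self.sim_time:.5g} ps",
            f"c_water: {self.c_water:.6g} Å⁻³",
            f"P: {self.P:.4g} +/- {err} cm/s",
        ]
        return "\n".join(lines)


def dividing_surfaces(traj: Trajectory, offset: float = 8.0) -> MembraneGeometry:
    """Place the dividing surfaces ``offset`` Å beyond the mean |z| of the
    phosphate particles (time-and-particle average)."""
    zp = traj.z("phosphate")
    mean_abs = float(np.abs(zp).mean())
    return MembraneGeometry(
        half_thickness=mean_abs + offset,
        phosphate_mean_abs_z=mean_abs,
        offset=offset,
    )


def detect_crossings(traj: Trajectory, geom: MembraneGeometry) -> list:
    """Scan every permeant for complete membrane crossings.

    Frames are labeled A (z < −h/2), M (|z| ≤ h/2) or B (z > +h/2).  A
    crossing is recorded whenever the most recent water label is followed
    by the opposite water label; re-entries into M that return to the same
    side do not count.  Frame-to-frame water→water jumps with |Δz| > Lz/2
    are periodic wraps through the contiguous water phase, not crossings.
    """
    h2 = geom.half_thickness
    lz = traj.box[:, 2]
    if h2 >= float(lz.min()) / 2:
        raise GeometryError(
            f"h/2 = {h2} Å does not fit inside the box (Lz/2 = {lz.min() / 2} Å)"
        )
    times = traj.times
    events = []
    perm = traj.require("permeant")
    z_all = traj.positions[:, perm, 2]
    for col, pid in enumerate(perm):
        z = z_all[:, col]
        region = np.where(z < -h2, -1, np.where(z > h2, 1, 0))
        last_side = 0  # 0 = no water frame seen yet
        last_frame = -1
        for i in np.nonzero(region)[0]:
            r = region[i]
            if last_side == 0 or r == last_side:
                last_side, last_frame = r, i
                continue
            # reached the opposite water phase
            direct = i - last_frame == 1
            if direct and abs(z[i] - z[last_frame]) > lz[i] / 2:
                # periodic wrap: water phases are contiguous across the boundary
                last_side, last_frame = r, i
                continue
            events.append(
                CrossingEvent(
                    particle=int(pid),
                    t_entry=float(times[last_frame]),
                    t_exit=float(times[i]),
                    direction="+z" if r > 0 else "-z",
                )
            )
            last_side, last_frame = r, i
    return events


def counting_permeability(
    traj: Trajectory, geom: MembraneGeometry
) -> PermeabilityResult:
    """Equilibrium counting-method permeability in cm/s.

    For 1D synthetic systems (lateral box 1 Å × 1 Å) the area A = 1 Å²
    enters both the rate normalization and c_water, so P is well-defined.
    """
    if traj.n_frames < 2:
        raise ValidationError("need at least two frames")
    events = detect_crossings(traj, geom)
    n = len(events)
    area = float((traj.box[:, 0] * traj.box[:, 1]).mean())
    sim_time = float(traj.times[-1] - traj.times[0])
    h2 = geom.half_thickness
    z = traj.z("permeant")
    lz = traj.box[:, 2]
    water_counts = (np.abs(z) > h2).sum(axis=1)
    water_volume = area * (lz - 2 * h2)
    c_water = float((water_counts / water_volume).mean())
    if c_water <= 0:
        raise ReferenceRegionError(
            "no permeant occupancy in the water phase; c_water is zero"
        )
    p_aps = n / (2 * area * sim_time * c_water)
    P = p_aps * ANGSTROM_PER_PS_TO_CM_PER_S
    return PermeabilityResult(
        n_crossings=n,
        events=events,
        area=area,
        sim_time=sim_time,
        c_water=c_water,
        P=P,
        P_err=(P / math.sqrt(n)) if n > 0 else math.nan,
        half_thickness=h2,
    )


def isd_permeability(
    F,
    D,
    geom: MembraneGeometry,
    T: float = DEFAULT_TEMPERATURE,
) -> float:
    """Inhomogeneous solubility–diffusivity permeability, in cm/s.

    1/P = ∫_{−h/2}^{+h/2} exp(F(z)/kBT)/D(z) dz with F referenced to zero
    in water, evaluated by adaptive quadrature (relative tolerance 1e-8).
    ``F`` and ``D`` may be callables or constants (kJ/mol and Å²/ps).
    """
    kt = kBT(T)
    h2 = geom.half_thickness
    f = F if callable(F) else (lambda z, _v=float(F): _v)
    d = D if callable(D) else (lambda z, _v=float(D): _v)
    probe = np.linspace(-h2, h2, 257)
    dvals = np.asarray([d(zz) for zz in probe], dtype=float)
    if np.any(dvals <= 0):
        raise ValidationError("D(z) must be positive on the membrane slab")

    def integrand(z):
        return math.exp(float(f(z)) / kt) / float(d(z))

    resistance, _ = quad(integrand, -h2, h2, epsrel=1e-8, limit=500)
    return (1.0 / resistance) * ANGSTROM_PER_PS_TO_CM_PER_S


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class CountingPermeabilityModel:
    """Counting-method permeability estimator.

    The membrane geometry is taken from the phosphate particles (offset
    rule) unless ``half_thickness`` or ``geometry`` overrides it.
    """

    def __init__(self, traj: Trajectory, offset: float = 8.0,
                 half_thickness: float = None, geometry: MembraneGeometry = None):
        self.traj = traj
        if geometry is not None:
            self.geometry = geometry
        elif half_thickness is not None:
            self.geometry = MembraneGeometry(half_thickness=half_thickness)
        else:
            self.geometry = dividing_surfaces(traj, offset)

    def fit(self) -> PermeabilityResult:
        return counting_permeability(self.traj, self.geometry)
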