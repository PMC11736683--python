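"""Free-energy profiles along the membrane normal by Boltzmann inversion.

The profile is F(z) = −kB·T·ln(hist(z)), with hist(z) the normalized
positional histogram of the permeant along z, shifted so the mean of F over
the water region is zero.  Statistical errors come from block averaging:
the trajectory is cut into ``n_blocks`` contiguous segments, the profile is
recomputed per block, and the per-bin standard error over blocks is
reported.

ΔG_m — the free-energy difference between the water phase and the membrane
center — is read off the shifted profile as −F(z=0)/kBT, positive when the
permeant prefers the membrane interior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, kBT
from .errors import ReferenceRegionError, ValidationError
from .trajectory import Trajectory

__all__ = [
    "FreeEnergyProfile",
    "free_energy_profile",
    "block_errors",
    "delta_g_membrane",
    "BoltzmannProfileModel",
    "BoltzmannProfileResults",
]


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile F(z) in kJ/mol.

    ``F`` is NaN in bins with zero counts (never ±inf).  ``F_err`` is NaN
    until block errors are attached.  ``water_region`` is the |z| interval
    used for the zero-of-energy shift.
    """

    bin_centers: np.ndarray
    F: np.ndarray
    counts: np.ndarray
    water_region: tuple
    T: float
    F_err: np.ndarray = None
    units: str = "kJ/mol"

    def __post_init__(self):
        if self.F_err is None:
            self.F_err = np.full_like(np.asarray(self.F, dtype=float), np.nan)

    @property
    def kBT(self) -> float:
        return kBT(self.T)

    def in_kBT(self) -> "FreeEnergyProfile":
        """The same profile with energies expressed in kBT units."""
        if self.units == "kBT":
            return self
        return FreeEnergyProfile(
            bin_centers=self.bin_centers,
            F=self.F / self.kBT,
            counts=self.counts,
            water_region=self.water_region,
            T=self.T,
            F_err=self.F_err / self.kBT,
            units="kBT",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.bin_centers,
                f"F_{self.units.replace('/', '_per_')}": self.F,
                "F_err": self.F_err,
                "counts": self.counts,
            }
        )


def _resolve_bins(traj: Trajectory, bins) -> np.ndarray:
    lz = float(traj.box[:, 2].max())
    if np.isscalar(bins):
        if isinstance(bins, (int, np.integer)):
            return np.linspace(-lz / 2, lz / 2, int(bins) + 1)
        # scalar float: bin width in Å
        n = max(int(np.ceil(lz / float(bins))), 1)
        return np.linspace(-lz / 2, lz / 2, n + 1)
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be a 1D increasing array")
    return edges


def _water_mask(centers: np.ndarray, water_region) -> np.ndarray:
    lo, hi = water_region
    return (np.abs(centers) >= lo) & (np.abs(centers) <= hi)


def _profile_from_z(z, edges, water_region, T) -> FreeEnergyProfile:
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges)
    with np.errstate(divide="ignore"):
        dens = counts / (counts.sum() * widths)
        F = np.where(counts > 0, -kBT(T) * np.log(np.where(counts > 0, dens, 1.0)), np.nan)
    mask = _water_mask(centers, water_region) & (counts > 0)
    if not mask.any():
        raise ReferenceRegionError(
            f"water region |z| in {water_region} contains no samples"
        )
    F = F - np.nanmean(F[mask])
    return FreeEnergyProfile(
        bin_centers=centers, F=F, counts=counts, water_region=tuple(water_region), T=T
    )


def free_energy_profile(
    traj: Trajectory,
    bins=0.5,
    water_region=None,
    T: float = DEFAULT_TEMPERATURE,
) -> FreeEnergyProfile:
    """Boltzmann-inverted permeant z-histogram, zeroed over the water region.

    Parameters
    ----------
    bins : int, float or array
        Bin count (int), bin width in Å (float, default 0.5) or explicit
        edges covering the box z-range.
    water_region : (lo, hi)
        |z| interval defining the water phase used as the zero of energy.
        Required — there is no universal default without a membrane
        geometry (see :func:`permeant.permeability.dividing_surfaces`).
    """
    if water_region is None:
        raise ValidationError(
            "water_region must be given as an (|z|min, |z|max) interval"
        )
    z = traj.z("permeant").ravel()
    edges = _resolve_bins(traj, bins)
    return _profile_from_z(z, edges, water_region, T)


def block_errors(
    traj: Trajectory,
    bins=0.5,
    water_region=None,
    T: float = DEFAULT_TEMPERATURE,
    n_blocks: int = 10,
) -> np.ndarray:
    """Per-bin standard error of F from contiguous block averages.

    The frames are split into ``n_blocks`` equal contiguous segments
    (trailing remainder dropped); the profile is recomputed per block and
    the standard error of the block-wise F values is returned, per bin.
    Bins undefined in some blocks use only the blocks where they are
    defined; bins defined in fewer than two blocks get NaN.
    """
    if n_blocks < 2:
        raise ValidationError("n_blocks must be at least 2")
    if water_region is None:
        raise ValidationError("water_region must be given")
    z = traj.z("permeant")
    block_len = traj.n_frames // n_blocks
    if block_len < 1:
        raise ValidationError(
            f"cannot split {traj.n_frames} frames into {n_blocks} blocks"
        )
    edges = _resolve_bins(traj, bins)
    block_F = []
    for b in range(n_blocks):
        zb = z[b * block_len : (b + 1) * block_len].ravel()
        prof = _profile_from_z(zb, edges, water_region, T)
        block_F.append(prof.F)
    block_F = np.array(block_F)  # (n_blocks, n_bins)
    n_def = np.sum(~np.isnan(block_F), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(block_F, axis=0, ddof=1)
    err = np.where(n_def >= 2, sd / np.sqrt(np.maximum(n_def, 1)), np.nan)
    return err


def delta_g_membrane(profile: FreeEnergyProfile) -> float:
    """ΔG_m in kBT units: F(water) − F(membrane center).

    Positive when the permeant prefers the membrane center over water.
    The center value is read from the bin containing z = 0.
    """
    i0 = int(np.argmin(np.abs(profile.bin_centers)))
    f0 = profile.F[i0]
    if not np.isfinite(f0):
        raise ReferenceRegionError("the bin containing z = 0 has no samples")
    f0_kt = f0 if profile.units == "kBT" else f0 / profile.kBT
    # water-region mean is zero by construction after the shift
    return -float(f0_kt)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class BoltzmannProfileModel:
    """Free-energy profile estimator for a permeant trajectory.

    Examples
    --------
    >>> model = BoltzmannProfileModel(traj, bins=0.5, water_region=(30, 40))
    >>> res = model.fit(n_blocks=10)
    >>> res.delta_g_m, res.profile.F
    """

    def __init__(self, traj: Trajectory, bins=0.5, water_region=None,
                 T: float = DEFAULT_TEMPERATURE):
        self.traj = traj
        self.bins = bins
        self.water_region = water_region
        self.T = T

    def fit(self, n_blocks: int = 10) -> "BoltzmannProfileResults":
        profile = free_energy_profile(
            self.traj, self.bins, self.water_region, self.T
        )
        if n_blocks and self.traj.n_frames >= 2 * n_blocks:
            profile.F_err = block_errors(
                self.traj, self.bins, self.water_region, self.T, n_blocks
            )
        return BoltzmannProfileResults(self, profile, n_blocks)


class BoltzmannProfileResults:
    """Fitted free-energy profile with block errors and ΔG_m."""

    def __init__(self, model, profile: FreeEnergyProfile, n_blocks: int):
        self.model = model
        self.profile = profile
        self.n_blocks = n_blocks

    @property
    def delta_g_m(self) -> float:
        """Water→membrane-center free-energy difference, in kBT."""
        return delta_g_membrane(self.profile)

    @property
    def delta_g_m_err(self) -> float:
        """Block-average error on ΔG_m, in kBT (NaN without block errors)."""
        i0 = int(np.argmin(np.abs(self.profile.bin_centers)))
        return float(self.profile.F_err[i0] / self.profile.kBT)

    def to_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary(self) -> str:
        p = self.profile
        n_def = int(np.sum(np.isfinite(p.F)))
        lines = [
            "Boltzmann-inversion free-energy profile",
            "=" * 46,
            f"frames: {self.model.traj.n_frames}   permeants: "
            f"{len(self.model.traj.select('permeant'))}",
            f"bins: {len(p.bin_centers)} ({n_def} sampled)   T: {p.T} K",
            f"water region |z|: [{p.water_region[0]:g}, {p.water_region[1]:g}] Å",
            f"block errors: {self.n_blocks} blocks",
            f"dG_m (water -> center): {self.delta_g_m:.3f} "
            f"+/- {self.delta_g_m_err:.3f} kBT",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, in_kBT: bool = True):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.profile.in_kBT() if in_kBT else self.profile
        ax.errorbar(p.bin_centers, p.F, yerr=p.F_err, fmt="-", capsize=2)
        ax.set_xlabel("z (Å)")
        ax.set_ylabel(f"F(z) ({p.units})")
        return ax
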