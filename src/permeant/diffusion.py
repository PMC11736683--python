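"""Diffusion coefficients from mean-square displacement.

The MSD is computed with the multiple-time-origin average over all
permeants (FFT algorithm, O(N log N) per particle), the diffusion
coefficient comes from an ordinary least-squares line through a fit
window, D = slope/(2·d) with d the dimensionality, and the periodic-box
hydrodynamic finite-size correction adds

    ΔD = kB·T·ξ / (6π·η·L),   ξ = 2.837297,

the leading-order cubic-lattice self-interaction term, where η is the
solvent shear viscosity and L the box edge.  The stick/slip boundary flag
and hydrodynamic radius R are recorded and enter only the optional
next-order term −kB·T·4πR²/(6π·η·3L³) (Hasimoto-type, off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_J, M2_PER_S_TO_A2_PER_PS
from .errors import ConfigurationError, ValidationError
from .trajectory import Trajectory

__all__ = [
    "XI_CUBIC",
    "MsdCurve",
    "DiffusionResult",
    "msd",
    "fit_diffusion",
    "pbc_correction_term",
    "pbc_correct",
    "MsdDiffusionModel",
]

#: Self-interaction constant of a simple cubic lattice of hydrodynamic images.
XI_CUBIC = 2.837297


@dataclass
class MsdCurve:
    """Mean-square displacement versus lag time."""

    lags: np.ndarray        # ps
    msd: np.ndarray         # Å²
    n_origins: np.ndarray   # time origins averaged per lag
    dimensionality: int = 3

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins)
        if np.any(np.diff(self.lags) <= 0):
            raise ValidationError("lags must be strictly increasing")
        if self.lags[0] == 0 and abs(self.msd[0]) > 1e-9:
            raise ValidationError("msd(0) must be 0")


@dataclass
class DiffusionResult:
    """Diffusion coefficient with optional finite-size correction."""

    D_pbc: float                    # Å²/ps
    D_corrected: float = None       # Å²/ps
    fit_window: tuple = None        # (ps, ps)
    boundary_condition: str = "stick"
    viscosity: float = None         # Pa·s
    box_length: float = None        # Å
    hydrodynamic_radius: float = None  # Å
    slope: float = None             # Å²/ps
    intercept: float = None         # Å²
    dimensionality: int = 3

    @property
    def correction_term(self) -> float:
        if self.D_corrected is None:
            return 0.0
        return self.D_corrected - self.D_pbc

    def summary(self) -> str:
        lines = [
            "MSD diffusion fit",
            "=" * 40,
            f"D_pbc: {self.D_pbc:.4g} Å²/ps "
            f"(slope/{2 * self.dimensionality} over window "
            f"{self.fit_window[0]:g}–{self.fit_window[1]:g} ps)",
        ]
        if self.D_corrected is not None:
            lines += [
                f"finite-size correction: +{self.correction_term:.4g} Å²/ps "
                f"(η={self.viscosity:g} Pa·s, L={self.box_length:g} Å, "
                f"{self.boundary_condition})",
                f"D_corrected: {self.D_corrected:.4g} Å²/ps",
            ]
        return "\n".join(lines)


def _msd_fft_single(r: np.ndarray) -> np.ndarray:
    """MSD over all time origins for one particle; r is (N, d)."""
    N = r.shape[0]
    nfft = 1 << (2 * N - 1).bit_length()
    S2 = np.zeros(N)
    for dim in range(r.shape[1]):
        f = np.fft.rfft(r[:, dim], n=nfft)
        acf = np.fft.irfft(f * f.conj(), n=nfft)[:N]
        S2 += acf
    counts = N - np.arange(N)
    S2 /= counts
    D = (r**2).sum(axis=1)
    # S1[m] = sum_{k=m}^{N-1} D[k] + sum_{k=0}^{N-1-m} D[k], normalized
    csum = np.concatenate([[0.0], np.cumsum(D)])
    total = csum[-1]
    m = np.arange(N)
    S1 = (total - csum[m]) + csum[N - m]
    S1 /= counts
    return S1 - 2 * S2


_AXES = {"x": 0, "y": 1, "z": 2}


def msd(traj: Trajectory, max_lag: float = None, role: str = "permeant",
        dims: str = "xyz") -> MsdCurve:
    """Multiple-time-origin MSD averaged over all particles of a role.

    Requires unwrapped coordinates.  ``max_lag`` (ps) defaults to half the
    trajectory length.  ``dims`` selects the axes (e.g. ``"z"`` for a 1D
    membrane-normal trajectory); the dimensionality of the fit follows it.
    """
    try:
        axes = [_AXES[c] for c in dims]
    except KeyError:
        raise ValidationError(f"dims must be a subset of 'xyz', got {dims!r}")
    if not axes:
        raise ValidationError("dims must name at least one axis")
    r_all = traj.unwrapped_positions()[:, traj.require(role), :][:, :, axes]
    n_frames = traj.n_frames
    if n_frames < 2:
        raise ValidationError("MSD needs at least two frames")
    dt = traj.dt
    if max_lag is None:
        max_lag = traj.times[-1] / 2
    n_lags = min(int(max_lag / dt) + 1, n_frames)
    acc = np.zeros(n_lags)
    for p in range(r_all.shape[1]):
        acc += _msd_fft_single(np.ascontiguousarray(r_all[:, p, :]))[:n_lags]
    acc /= r_all.shape[1]
    acc[0] = 0.0  # exact by definition; clears FFT round-off
    counts = (n_frames - np.arange(n_lags)) * r_all.shape[1]
    return MsdCurve(
        lags=dt * np.arange(n_lags),
        msd=acc,
        n_origins=counts,
        dimensionality=len(axes),
    )


def fit_diffusion(curve: MsdCurve, window: tuple) -> DiffusionResult:
    """OLS line through the MSD inside ``window``; D = slope/(2·d)."""
    lo, hi = window
    if lo < curve.lags[0] or hi > curve.lags[-1] or lo >= hi:
        raise ValidationError(
            f"fit window {window} outside lag range "
            f"[{curve.lags[0]}, {curve.lags[-1]}]"
        )
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 5:
        raise ValidationError("fit window must contain at least 5 MSD points")
    slope, intercept = np.polyfit(curve.lags[mask], curve.msd[mask], 1)
    return DiffusionResult(
        D_pbc=float(slope) / (2 * curve.dimensionality),
        fit_window=(float(lo), float(hi)),
        slope=float(slope),
        intercept=float(intercept),
        dimensionality=curve.dimensionality,
    )


def pbc_correction_term(
    T: float, eta: float, L: float, bc: str = "stick", R: float = None,
    higher_order: bool = False,
) -> float:
    """Additive finite-size correction in Å²/ps.

    Leading order: kB·T·ξ/(6π·η·L).  With ``higher_order`` and a radius R,
    the next-order term −kB·T·4πR²/(18π·η·L³) is included.
    """
    if T <= 0 or eta is None or eta <= 0 or L <= 0:
        raise ConfigurationError("T, η and L must all be positive")
    if bc not in ("stick", "slip"):
        raise ConfigurationError("boundary condition must be 'stick' or 'slip'")
    L_m = L * 1e-10
    term = KB_J * T * XI_CUBIC / (6 * math.pi * eta * L_m)  # m²/s
    if higher_order:
        if R is None or R <= 0:
            raise ConfigurationError("higher-order term needs a positive radius R")
        R_m = R * 1e-10
        term -= KB_J * T * 4 * math.pi * R_m**2 / (18 * math.pi * eta * L_m**3)
    return term * M2_PER_S_TO_A2_PER_PS


def pbc_correct(
    result: DiffusionResult,
    T: float = DEFAULT_TEMPERATURE,
    eta: float = None,
    L: float = None,
    bc: str = "stick",
    R: float = None,
    higher_order: bool = False,
) -> DiffusionResult:
    """Apply the hydrodynamic finite-size correction to a fitted D.

    η (Pa·s) and L (Å) are required; there is no default viscosity.  The
    stick/slip flag and R are recorded in the result and affect only the
    optional higher-order term.
    """
    if eta is None:
        raise ConfigurationError(
            "the finite-size correction needs the solvent viscosity η (Pa·s)"
        )
    if L is None or L <= 0:
        raise ConfigurationError("the finite-size correction needs the box edge L (Å)")
    term = pbc_correction_term(T, eta, L, bc, R, higher_order)
    return replace(
        result,
        D_corrected=result.D_pbc + term,
        boundary_condition=bc,
        viscosity=eta,
        box_length=L,
        hydrodynamic_radius=R,
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

#: Fit window used for long trajectories, ps (1–50 ns).
LONG_WINDOW = (1000.0, 50000.0)


def default_window(curve: MsdCurve, total_time: float = None) -> tuple:
    """1–50 ns for long runs, else 5%–25% of the total time.

    The 1–50 ns window is only statistically sound when it is a small
    fraction of the run (≥200 ns of data); shorter runs use a window that
    scales with the trajectory so the MSD estimates in it stay
    well-averaged.
    """
    if total_time is None:
        total_time = 2 * curve.lags[-1]
    if total_time >= 4 * LONG_WINDOW[1] and curve.lags[-1] >= LONG_WINDOW[1]:
        return LONG_WINDOW
    lo = max(0.05 * total_time, curve.lags[1])
    hi = min(0.25 * total_time, curve.lags[-1])
    return (lo, hi)


class MsdDiffusionModel:
    """Diffusion-coefficient estimator from MSD slopes.

    Examples
    --------
    >>> res = MsdDiffusionModel(traj).fit()
    >>> res = pbc_correct(res, T=310, eta=1e-3, L=203)
    """

    def __init__(self, traj: Trajectory, max_lag: float = None,
                 role: str = "permeant", dims: str = "xyz"):
        self.traj = traj
        self.curve = msd(traj, max_lag, role, dims)

    def fit(self, window: tuple = None, T: float = DEFAULT_TEMPERATURE,
            eta: float = None, bc: str = "stick", R: float = None) -> DiffusionResult:
        if window is None:
            total = float(self.traj.times[-1] - self.traj.times[0])
            window = default_window(self.curve, total)
        res = fit_diffusion(self.curve, window)
        if eta is not None:
            L = float(self.traj.box[:, 0].mean())
            res = pbc_correct(res, T=T, eta=eta, L=L, bc=bc, R=R)
        return res
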