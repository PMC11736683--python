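"""Trajectory container and I/O.

The :class:`Trajectory` is the common currency of every analysis stage:
time-ordered particle coordinates in an orthorhombic periodic box, with a
role label per particle (``permeant``, ``phosphate``,
``cavity_residue:<name>``, ``solvent`` or ``other``).

Two I/O routes are supported:

* standard structure/coordinate formats (GRO/PDB + XTC/TRR/DCD, or any
  combination MDAnalysis can read), with roles assigned from selection
  strings;
* a plain-text tabular dialect (TSV) used for fixtures and synthetic runs,
  which round-trips exactly.

Internal conventions: lengths in Å, times in ps, the membrane normal is the
z axis and the bilayer midplane sits at z = 0 (use :func:`center_membrane`
for membrane trajectories read from MD output).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, LabelingError, UnwrapError, ValidationError

_TIME_RTOL = 1e-9

#: Magic token on the first header line of the tabular dialect.
_MAGIC = "#ptraj"


@dataclass
class Trajectory:
    """Time series of particle positions in a periodic orthorhombic box.

    Parameters
    ----------
    times : (n_frames,) array
        Frame times in ps, strictly increasing on a uniform grid.
    positions : (n_frames, n_particles, 3) array
        Wrapped coordinates in Å.
    box : (n_frames, 3) array
        Orthorhombic box edge lengths in Å per frame.
    labels : sequence of str
        One role label per particle.
    unwrapped : optional (n_frames, n_particles, 3) array
        Unwrapped coordinates, when available (required for MSD analysis).
    periodic : 3-tuple of bool
        Periodicity flags per axis.
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    labels: list = field(default_factory=list)
    unwrapped: np.ndarray | None = None
    periodic: tuple = (True, True, True)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if box.ndim == 1:
            box = np.tile(box, (len(self.times), 1))
        self.box = box
        self.labels = list(self.labels)
        if self.unwrapped is not None:
            self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self):
        n_frames = len(self.times)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError(
                f"positions must have shape (n_frames, n_particles, 3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] != n_frames:
            raise ValidationError("positions frame count does not match times")
        if self.box.shape != (n_frames, 3):
            raise ValidationError("box must have shape (n_frames, 3)")
        if len(self.labels) != self.positions.shape[1]:
            raise ValidationError(
                f"{len(self.labels)} labels for "
                f"{self.positions.shape[1]} particles"
            )
        if n_frames > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValidationError("times must be strictly increasing")
            dt = dts[0]
            if np.any(np.abs(dts - dt) > _TIME_RTOL * max(abs(dt), 1.0)):
                raise ValidationError("times must lie on a uniform grid")
        if not np.all(self.box > 0):
            raise ValidationError("box edges must be positive in all frames")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("positions contain non-finite values")
        if self.unwrapped is not None:
            if self.unwrapped.shape != self.positions.shape:
                raise ValidationError("unwrapped shape mismatch")
            if not np.all(np.isfinite(self.unwrapped)):
                raise ValidationError("unwrapped positions contain non-finite values")

    # -- basic queries ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Frame interval in ps (0 for a single-frame trajectory)."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    def select(self, role: str) -> np.ndarray:
        """Indices of particles whose label equals ``role``.

        A trailing ``*`` matches by prefix, e.g. ``"cavity_residue:*"``.
        """
        labels = np.asarray(self.labels)
        if role.endswith("*"):
            prefix = role[:-1]
            mask = np.char.startswith(labels.astype(str), prefix)
        else:
            mask = labels == role
        return np.nonzero(mask)[0]

    def require(self, role: str) -> np.ndarray:
        idx = self.select(role)
        if idx.size == 0:
            raise LabelingError(f"no particles labeled {role!r} in trajectory")
        return idx

    def z(self, role: str = "permeant") -> np.ndarray:
        """(n_frames, n_role_particles) z coordinates of a role group."""
        return self.positions[:, self.require(role), 2]

    def unwrapped_positions(self) -> np.ndarray:
        if self.unwrapped is None:
            raise UnwrapError(
                "trajectory has only wrapped coordinates; MSD analysis needs "
                "unwrapped ones — re-read with unwrapping or use a generator "
                "that stores them"
            )
        return self.unwrapped

    def role_counts(self) -> dict:
        vals, counts = np.unique(np.asarray(self.labels, dtype=str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def time_reversed(self) -> "Trajectory":
        """The same path traversed backwards (same time grid)."""
        unw = None if self.unwrapped is None else self.unwrapped[::-1].copy()
        return Trajectory(
            times=self.times.copy(),
            positions=self.positions[::-1].copy(),
            box=self.box[::-1].copy(),
            labels=list(self.labels),
            unwrapped=unw,
            periodic=self.periodic,
        )

    def __eq__(self, other):
        if not isinstance(other, Trajectory):
            return NotImplemented
        same_unwrapped = (self.unwrapped is None) == (other.unwrapped is None)
        if same_unwrapped and self.unwrapped is not None:
            same_unwrapped = np.allclose(self.unwrapped, other.unwrapped, atol=1e-6)
        return (
            self.labels == other.labels
            and self.positions.shape == other.positions.shape
            and np.allclose(self.times, other.times, atol=1e-9)
            and np.allclose(self.positions, other.positions, atol=1e-6)
            and np.allclose(self.box, other.box, atol=1e-6)
            and same_unwrapped
        )


def center_membrane(traj: Trajectory) -> Trajectory:
    """Recenter each frame so the bilayer midplane sits at z = 0.

    The midplane is estimated per frame as the mean z of the
    phosphate-labeled particles; all z coordinates are shifted and
    re-wrapped into (−Lz/2, Lz/2].
    """
    idx = traj.require("phosphate")
    mid = traj.positions[:, idx, 2].mean(axis=1)  # (n_frames,)
    pos = traj.positions.copy()
    pos[:, :, 2] -= mid[:, None]
    lz = traj.box[:, 2][:, None]
    pos[:, :, 2] -= np.round(pos[:, :, 2] / lz) * lz
    unw = None
    if traj.unwrapped is not None:
        unw = traj.unwrapped.copy()
        unw[:, :, 2] -= mid[:, None]
    return replace(traj, positions=pos, unwrapped=unw)


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory in the package tabular dialect (TSV).

    The format is plain text: a header line with particle count, frame
    interval and (constant) box, one comment line naming the columns, then
    one row per frame per particle.  Output is byte-stable: the same
    trajectory always serializes to the same bytes (coordinates printed to
    1e-6 Å).
    """
    if traj.n_frames > 1 and not np.allclose(
        traj.box, traj.box[0], rtol=0, atol=1e-9
    ):
        raise ValidationError(
            "tabular dialect stores a single box; this trajectory has a "
            "time-varying box"
        )
    box = traj.box[0] if traj.n_frames else np.zeros(3)
    has_unw = traj.unwrapped is not None
    t0 = traj.times[0] if traj.n_frames else 0.0
    lines = [
        f"{_MAGIC}\tn_particles={traj.n_particles}\tn_frames={traj.n_frames}"
        f"\tdt_ps={traj.dt:.9g}\tt0_ps={t0:.9g}"
        f"\tbox={box[0]:.6f},{box[1]:.6f},{box[2]:.6f}"
        f"\tunwrapped={int(has_unw)}"
        f"\tperiodic={','.join(str(int(p)) for p in traj.periodic)}",
        "#frame\tid\trole\tx\ty\tz" + ("\tux\tuy\tuz" if has_unw else ""),
    ]
    for i in range(traj.n_frames):
        for j in range(traj.n_particles):
            x, y, z = traj.positions[i, j]
            row = f"{i}\t{j}\t{traj.labels[j]}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
            if has_unw:
                ux, uy, uz = traj.unwrapped[i, j]
                row += f"\t{ux:.6f}\t{uy:.6f}\t{uz:.6f}"
            lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def _read_tabular(path) -> Trajectory:
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise FormatError(f"{path}: not a tabular trajectory (missing {_MAGIC} header)")
    header = {}
    for tok in lines[0].split("\t")[1:]:
        key, _, val = tok.partition("=")
        header[key] = val
    try:
        n_particles = int(header["n_particles"])
        n_frames = int(header["n_frames"])
        dt = float(header["dt_ps"])
        t0 = float(header.get("t0_ps", "0"))
        box = np.array([float(v) for v in header["box"].split(",")])
        has_unw = bool(int(header.get("unwrapped", "0")))
        periodic = tuple(
            bool(int(v)) for v in header.get("periodic", "1,1,1").split(",")
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed header: {exc}") from exc

    positions = np.empty((n_frames, n_particles, 3))
    unwrapped = np.empty((n_frames, n_particles, 3)) if has_unw else None
    labels = [None] * n_particles
    n_rows = 0
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            fi, pj = int(parts[0]), int(parts[1])
            role = parts[2]
            xyz = [float(v) for v in parts[3:6]]
            if has_unw:
                uxyz = [float(v) for v in parts[6:9]]
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad record {line!r}", frame=n_rows // max(n_particles, 1)) from exc
        if not (0 <= fi < n_frames and 0 <= pj < n_particles):
            raise FormatError(f"{path}: frame/particle index out of range", frame=fi)
        positions[fi, pj] = xyz
        if has_unw:
            unwrapped[fi, pj] = uxyz
        if labels[pj] is None:
            labels[pj] = role
        elif labels[pj] != role:
            raise FormatError(
                f"{path}: particle {pj} has conflicting role labels", frame=fi
            )
        n_rows += 1
    if n_rows != n_frames * n_particles:
        raise FormatError(
            f"{path}: expected {n_frames * n_particles} records, got {n_rows}"
        )
    labels = [lbl if lbl is not None else "other" for lbl in labels]
    times = t0 + dt * np.arange(n_frames)
    if n_frames == 0:
        positions = positions.reshape(0, n_particles, 3)
    return Trajectory(
        times=times,
        positions=positions,
        box=np.tile(box, (n_frames, 1)) if n_frames else np.zeros((0, 3)),
        labels=labels,
        unwrapped=unwrapped,
        periodic=periodic,
    )


_TABULAR_SUFFIXES = {".tsv", ".txt", ".ptraj", ".dat"}


def read_trajectory(path, topology=None, role_map=None) -> Trajectory:
    """Read a trajectory from disk.

    Files with a tabular-dialect suffix (``.tsv``, ``.txt``, ``.ptraj``,
    ``.dat``) are parsed directly; anything else is handed to MDAnalysis,
    with ``topology`` as the structure file when the coordinate format
    needs one.

    Parameters
    ----------
    role_map : dict, optional
        Mapping of MDAnalysis selection strings to role labels, e.g.
        ``{"name PO4": "phosphate", "resname O2": "permeant"}``.  Particles
        matched by no selection are labeled ``"other"``.  Ignored for the
        tabular dialect (roles are stored in the file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TABULAR_SUFFIXES:
        return _read_tabular(path)
    return _read_mdanalysis(path, topology, role_map)


def _read_mdanalysis(path, topology, role_map) -> Trajectory:
    import MDAnalysis as mda

    try:
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises a zoo of error types
        raise FormatError(f"{path}: unreadable trajectory: {exc}") from exc

    n_particles = len(u.atoms)
    labels = ["other"] * n_particles
    if role_map:
        for selection, role in role_map.items():
            try:
                group = u.select_atoms(selection)
            except Exception as exc:
                raise LabelingError(
                    f"bad selection {selection!r}: {exc}"
                ) from exc
            for ix in group.ix:
                labels[ix] = role

    times, positions, boxes = [], [], []
    for i, ts in enumerate(u.trajectory):
        if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
            raise FormatError(f"{path}: missing or degenerate box", frame=i)
        if not np.allclose(ts.dimensions[3:6], 90.0, atol=1e-3):
            raise ValidationError(
                f"{path}: only orthorhombic boxes are supported (frame {i})"
            )
        times.append(float(ts.time))
        positions.append(ts.positions.copy())
        boxes.append(ts.dimensions[:3].copy())
    times = np.asarray(times)
    if len(times) > 1 and np.allclose(times, times[0]):
        # some readers report no time information; fall back to frame index
        times = np.arange(len(times), dtype=float)
    return Trajectory(
        times=times,
        positions=np.asarray(positions),
        box=np.asarray(boxes),
        labels=labels,
    )
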