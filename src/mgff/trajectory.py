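"""Trajectory container for tagged atom subsets.

Holds time-ordered positions for a handful of *roles* (Mg, water oxygen Ow,
Cl, phosphate oxygen OP, ...) together with per-frame orthorhombic box
lengths.  This deliberately carries only what the analyses need - no
topology, no velocities.

Two readers are provided: a plain per-frame XYZ-with-box text format (see
:func:`read_xyzbox`) used for fixtures and interchange, and a GRO/XTC/TRR
loader backed by MDAnalysis (optional dependency, imported lazily).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError

__all__ = ["Trajectory", "minimum_image", "pair_distances", "read_xyzbox", "write_xyzbox", "load_md"]


@dataclass
class Trajectory:
    """Time-ordered positions of tagged atom groups with periodic box.

    Parameters
    ----------
    times : (n_frames,) array, ps, strictly increasing.
    coords : mapping role -> (n_frames, n_atoms_role, 3) array, nm, wrapped
        into the box.  Group sizes are constant across frames by construction.
    box : (n_frames, 3) array of orthorhombic box lengths, nm.  Triclinic
        boxes are not supported.
    """

    times: np.ndarray
    coords: dict[str, np.ndarray]
    box: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise InputError("times must be a nonempty 1-D array")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if self.box.shape != (self.times.size, 3):
            raise GeometryError(
                f"box must have shape (n_frames, 3); got {self.box.shape} "
                "(triclinic boxes are not supported)"
            )
        if np.any(self.box <= 0):
            raise GeometryError("box lengths must be positive")
        clean = {}
        for role, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[0] != self.times.size or xyz.shape[2] != 3:
                raise InputError(
                    f"coords[{role!r}] must have shape (n_frames, n_atoms, 3); got {xyz.shape}"
                )
            clean[role] = xyz
        self.coords = clean

    @property
    def n_frames(self) -> int:
        return self.times.size

    def n_atoms(self, role: str) -> int:
        return self.group(role).shape[1]

    def group(self, role: str) -> np.ndarray:
        if role not in self.coords:
            raise InputError(f"trajectory has no role {role!r}; roles: {sorted(self.coords)}")
        return self.coords[role]

    def wrapped(self) -> "Trajectory":
        """Return a copy with all coordinates wrapped into [0, box)."""
        coords = {r: np.mod(x, self.box[:, None, :]) for r, x in self.coords.items()}
        return Trajectory(self.times.copy(), coords, self.box.copy())


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement
    vectors; ``box`` broadcasts against the last axis of ``disp``."""
    return disp - box * np.round(disp / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distances between two coordinate groups per frame.

    ``a``: (n_frames, n_a, 3), ``b``: (n_frames, n_b, 3), ``box``:
    (n_frames, 3).  Returns (n_frames, n_a, n_b).
    """
    disp = a[:, :, None, :] - b[:, None, :, :]
    disp = minimum_image(disp, box[:, None, None, :])
    return np.sqrt(np.sum(disp * disp, axis=-1))


# ---------------------------------------------------------------------------
# Plain-text XYZ-with-box format
#
#   <n_atoms>
#   t=<time/ps> box=<lx> <ly> <lz>
#   <role> <x> <y> <z>        (nm; role repeated per atom, grouped)
#   ...next frame...
# ---------------------------------------------------------------------------


def write_xyzbox(traj: Trajectory, path) -> None:
    """Write a trajectory in the plain XYZ-with-box text format."""
    roles = sorted(traj.coords)
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            n_total = sum(traj.coords[r].shape[1] for r in roles)
            fh.write(f"{n_total}\n")
            bx, by, bz = traj.box[i]
            fh.write(f"t={traj.times[i]:.6f} box={bx:.6f} {by:.6f} {bz:.6f}\n")
            for role in roles:
                for x, y, z in traj.coords[role][i]:
                    fh.write(f"{role} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyzbox(path) -> Trajectory:
    """Read a trajectory written by :func:`write_xyzbox`."""
    times, boxes = [], []
    frames: list[dict[str, list]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise InputError(f"bad atom count at line {i + 1}: {lines[i]!r}") from exc
        header = lines[i + 1].split()
        t = float(header[0].split("=")[1])
        box = [float(header[1].split("=")[1]), float(header[2]), float(header[3])]
        frame: dict[str, list] = {}
        for j in range(n):
            parts = lines[i + 2 + j].split()
            frame.setdefault(parts[0], []).append([float(p) for p in parts[1:4]])
        times.append(t)
        boxes.append(box)
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise InputError(f"no frames found in {path}")
    roles = sorted(frames[0])
    coords = {r: np.array([f[r] for f in frames], dtype=float) for r in roles}
    return Trajectory(np.array(times), coords, np.array(boxes))


def load_md(topology, trajectory=None, selections: dict[str, str] | None = None) -> Trajectory:
    """Load a GRO(+XTC/TRR) trajectory through MDAnalysis.

    ``selections`` maps role names to MDAnalysis selection strings, e.g.
    ``{"Mg": "name MG", "Ow": "name OW"}``.  Requires the optional
    MDAnalysis dependency.
    """
    import MDAnalysis as mda  # deferred: optional dependency

    if selections is None:
        selections = {"Mg": "name MG Mg MG2+", "Ow": "name OW O"}
    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    groups = {role: u.select_atoms(sel) for role, sel in selections.items()}
    empty = [r for r, g in groups.items() if g.n_atoms == 0]
    if empty:
        raise InputError(f"selections matched no atoms for roles: {empty}")
    times, boxes = [], []
    coords: dict[str, list] = {r: [] for r in groups}
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:6], 90.0):
            raise GeometryError("only orthorhombic boxes are supported")
        times.append(ts.time)
        boxes.append(dims[:3] / 10.0)  # Angstrom -> nm
        for r, g in groups.items():
            coords[r].append(g.positions / 10.0)
    return Trajectory(
        np.array(times), {r: np.array(c) for r, c in coords.items()}, np.array(boxes)
    )
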