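"""XYZ trajectory I/O, velocity derivation and bridge atom selection.

The XYZ dialect is the plain multi-frame format: an atom-count line, a
comment line (the writer stamps it with ``t= <time fs>``), then one
``label x y z`` line per atom.  Velocity files use the identical layout with
Å/fs components.  The frame spacing ``dt`` is supplied by the caller, never
parsed from the file; if a comment carries ``t=`` the reader checks it for
consistency and logs a warning on mismatch.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "BridgeDefinition",
    "XYZParseError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "derive_velocities",
    "bridge_atoms",
]


class XYZParseError(ValueError):
    """Malformed XYZ input."""


@dataclass
class Trajectory:
    """An ordered stack of labelled atomic positions, optionally velocities.

    positions: (n_frames, n_atoms, 3) Å; velocities: same shape, Å/fs, or
    ``None``; dt: inter-frame spacing in fs; t0: time of the first frame.
    """

    labels: list[str]
    positions: np.ndarray
    velocities: np.ndarray | None = None
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("label count does not match atom count")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Absolute frame times in fs."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    def with_velocities(self, velocities: np.ndarray) -> "Trajectory":
        return replace(self, velocities=np.asarray(velocities, float))


@dataclass(frozen=True)
class BridgeDefinition:
    """Donor / proton / acceptor atom indices (0-based) of one O-H...O bridge.

    ``label`` is free text for reports, e.g. the chemical atom names
    "O8-HBP1...O1".
    """

    donor_index: int
    proton_index: int
    acceptor_index: int
    label: str = ""

    def __post_init__(self) -> None:
        idx = (self.donor_index, self.proton_index, self.acceptor_index)
        if len(set(idx)) != 3:
            raise ValueError(f"bridge indices must be distinct, got {idx}")
        if min(idx) < 0:
            raise ValueError(f"bridge indices must be non-negative, got {idx}")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.donor_index, self.proton_index, self.acceptor_index)


_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eEdD]+)")


def read_xyz_trajectory(path, dt: float, t0: float = 0.0,
                        velocity_path=None) -> Trajectory:
    """Read a (multi-frame) XYZ file into a :class:`Trajectory`.

    Atom labels are taken from the first frame; every later frame must
    repeat the same atom count and label order or an :class:`XYZParseError`
    naming the offending (0-based) frame is raised.  Non-numeric coordinates
    raise an error naming the (1-based) line number.
    """
    labels, frames = _read_xyz_frames(path)
    traj = Trajectory(labels=labels, positions=np.array(frames), dt=dt, t0=t0)
    _check_time_comments(path, dt, t0)
    if velocity_path is not None:
        vlabels, vframes = _read_xyz_frames(velocity_path)
        if vlabels != labels or len(vframes) != len(frames):
            raise XYZParseError(
                f"velocity file {velocity_path} does not match the "
                f"trajectory (labels or frame count differ)"
            )
        traj = traj.with_velocities(np.array(vframes))
    return traj


def _read_xyz_frames(path):
    labels: list[str] | None = None
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_lines = len(lines)
    frame_idx = 0
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"{path}: line {i + 1}: expected an atom count, "
                f"got {lines[i]!r}"
            ) from None
        if i + 1 + n_atoms >= n_lines + 1:
            raise XYZParseError(
                f"{path}: frame {frame_idx} is truncated "
                f"(expected {n_atoms} atom lines)"
            )
        frame_labels = []
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            ln = i + 2 + a
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}: line {ln + 1}: expected 'label x y z', "
                    f"got {lines[ln]!r}"
                )
            frame_labels.append(parts[0])
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise XYZParseError(
                    f"{path}: line {ln + 1}: non-numeric coordinate in "
                    f"{lines[ln]!r}"
                ) from None
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels or n_atoms != len(labels):
            raise XYZParseError(
                f"{path}: frame {frame_idx}: atom count or labels differ "
                f"from frame 0"
            )
        frames.append(coords)
        i += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return labels, frames


def _check_time_comments(path, dt: float, t0: float) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        m = _TIME_RE.search(lines[i + 1]) if i + 1 < len(lines) else None
        if m:
            try:
                t_file = float(m.group(1).replace("D", "e").replace("d", "e"))
            except ValueError:
                t_file = None
            if t_file is not None:
                expected = t0 + frame_idx * dt
                if abs(t_file - expected) > 1e-6 * max(1.0, abs(expected)):
                    logger.warning(
                        "%s: frame %d comment time %.6f fs does not match "
                        "dt-derived time %.6f fs", path, frame_idx, t_file,
                        expected,
                    )
        i += 2 + n_atoms
        frame_idx += 1


def write_xyz_trajectory(traj: Trajectory, path, velocity_path=None) -> None:
    """Write a trajectory as standard XYZ with ``t= <fs>`` comments.

    Coordinates are printed with 9 decimal places.  If ``velocity_path`` is
    given and the trajectory carries velocities, a companion file in the
    identical layout (Å/fs) is written.
    """
    if traj.n_frames == 0:
        raise ValueError("refusing to write a trajectory with zero frames")
    _write_frames(path, traj.labels, traj.positions, traj.times)
    if velocity_path is not None:
        if traj.velocities is None:
            raise ValueError("trajectory has no velocities to write")
        _write_frames(velocity_path, traj.labels, traj.velocities, traj.times)


def _write_frames(path, labels, data, times) -> None:
    n_atoms = len(labels)
    with open(path, "w") as fh:
        for frame, t in zip(data, times):
            fh.write(f"{n_atoms}\n")
            fh.write(f"t= {t:.6f} fs\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.9f} {y:.9f} {z:.9f}\n")


def derive_velocities(traj: Trajectory) -> Trajectory:
    """Finite-difference velocities from positions.

    Central differences v(t_i) = (x(t_{i+1}) - x(t_{i-1})) / (2 dt) at
    interior frames; one-sided differences at the two ends, so the output
    has the same frame count (the end frames carry first-order bias).
    Requires at least 3 frames.
    """
    if traj.n_frames < 3:
        raise ValueError(
            f"need at least 3 frames to derive velocities, "
            f"got {traj.n_frames}"
        )
    x = traj.positions
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * traj.dt)
    v[0] = (x[1] - x[0]) / traj.dt
    v[-1] = (x[-1] - x[-2]) / traj.dt
    return traj.with_velocities(v)


def bridge_atoms(traj: Trajectory, bridge: BridgeDefinition) -> np.ndarray:
    """Per-frame (donor, proton, acceptor) coordinates, shape (n, 3, 3)."""
    for idx in bridge.indices:
        if idx >= traj.n_atoms:
            raise IndexError(
                f"bridge atom index {idx} out of range for a trajectory "
                f"with {traj.n_atoms} atoms"
            )
    return traj.positions[:, list(bridge.indices), :]
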