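"""Trajectory snapshot container and on-disk formats.

Snapshots are stored struct-of-arrays for speed; :class:`ParticleState`
offers a per-particle record view.  Two text formats are supported: the
package's own flat CSV dialect (columns ``t,id,label,x,y,z,vx,vy,vz,radius``,
all snapshots concatenated) and a reader for the LAMMPS/LIGGGHTS text dump
format (``ITEM: TIMESTEP`` / ``ITEM: ATOMS`` sections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CSV_COLUMNS = ["t", "id", "label", "x", "y", "z", "vx", "vy", "vz", "radius"]


@dataclass(frozen=True)
class ParticleState:
    id: int
    label: int
    position: np.ndarray
    velocity: np.ndarray
    radius: float
    mass: float


@dataclass
class TrajectorySnapshot:
    """Timestamped particle positions, velocities and labels."""

    time: float
    revolutions: float
    ids: np.ndarray          # (n,) int
    labels: np.ndarray       # (n,) int, values in {1, 2}
    positions: np.ndarray    # (n, 3) m
    velocities: np.ndarray   # (n, 3) m/s
    radii: np.ndarray        # (n,) m
    masses: np.ndarray = field(default=None)  # (n,) kg, optional

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must have shape (n, 3)")
        if len(self.labels) != n or len(self.radii) != n:
            raise ValueError("per-particle arrays must share a length")

    @property
    def n_particles(self) -> int:
        return len(self.ids)

    @property
    def particles(self) -> Iterator[ParticleState]:
        masses = self.masses if self.masses is not None else np.full(
            self.n_particles, np.nan)
        for k in range(self.n_particles):
            yield ParticleState(int(self.ids[k]), int(self.labels[k]),
                                self.positions[k], self.velocities[k],
                                float(self.radii[k]), float(masses[k]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.time, "id": self.ids, "label": self.labels,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "vx": self.velocities[:, 0], "vy": self.velocities[:, 1],
            "vz": self.velocities[:, 2], "radius": self.radii,
        })


def _check_monotone(snapshots: Sequence[TrajectorySnapshot]) -> None:
    times = [s.time for s in snapshots]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("snapshot times must be strictly increasing")
    counts = {s.n_particles for s in snapshots}
    if len(counts) > 1:
        raise ValueError("particle count must be constant across snapshots")


def write_trajectory_csv(snapshots: Sequence[TrajectorySnapshot],
                         path: str | Path) -> None:
    _check_monotone(snapshots)
    frames = [s.to_frame() for s in snapshots]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path, rpm: float = 0.0,
                        ) -> list[TrajectorySnapshot]:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    out = []
    for t, grp in df.groupby("t", sort=True):
        out.append(TrajectorySnapshot(
            time=float(t), revolutions=rpm * float(t) / 60.0,
            ids=grp["id"].to_numpy(np.int64),
            labels=grp["label"].to_numpy(np.int64),
            positions=grp[["x", "y", "z"]].to_numpy(float),
            velocities=grp[["vx", "vy", "vz"]].to_numpy(float),
            radii=grp["radius"].to_numpy(float)))
    _check_monotone(out)
    return out


def read_liggghts_dump(path: str | Path, timestep_dt: float = 1.0,
                       rpm: float = 0.0, default_radius: float = 1.0,
                       ) -> list[TrajectorySnapshot]:
    """Parse a LAMMPS/LIGGGHTS-style text dump into snapshots.

    ``timestep_dt`` converts integer timestep counters to seconds.  The
    ``ITEM: ATOMS`` header names the columns; ``id``/``type``/``x y z`` are
    required, velocities and radius optional (zero / ``default_radius``).
    """
    snapshots: list[TrajectorySnapshot] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ITEM: TIMESTEP"):
            step = int(lines[i + 1].strip())
            i += 2
            n_atoms = None
            cols: list[str] = []
            while i < len(lines) and not lines[i].startswith("ITEM: ATOMS"):
                if lines[i].startswith("ITEM: NUMBER OF ATOMS"):
                    n_atoms = int(lines[i + 1].strip())
                    i += 2
                else:
                    i += 1
            if i >= len(lines):
                break
            cols = lines[i].split()[2:]
            i += 1
            if n_atoms is None:
                raise ValueError("dump lacks ITEM: NUMBER OF ATOMS")
            rows = [lines[i + k].split() for k in range(n_atoms)]
            i += n_atoms
            data = {c: np.array([r[j] for r in rows], float)
                    for j, c in enumerate(cols)}
            for req in ("id", "type", "x", "y", "z"):
                if req not in data:
                    raise ValueError(f"dump ATOMS section lacks column {req!r}")
            n = n_atoms
            t = step * timestep_dt
            vel = np.column_stack([data.get(c, np.zeros(n))
                                   for c in ("vx", "vy", "vz")])
            rad = data.get("radius", np.full(n, default_radius))
            order = np.argsort(data["id"], kind="stable")
            snapshots.append(TrajectorySnapshot(
                time=t, revolutions=rpm * t / 60.0,
                ids=data["id"][order].astype(np.int64),
                labels=data["type"][order].astype(np.int64),
                positions=np.column_stack(
                    [data["x"], data["y"], data["z"]])[order],
                velocities=vel[order], radii=rad[order]))
        else:
            i += 1
    _check_monotone(snapshots)
    return snapshots
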