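"""Particle trajectories as time-stamped 3-D positions.

The :class:`Trajectory` container is the raw material of mean-square-
displacement analysis.  Positions are stored in SI units (meters, seconds);
the CSV and XYZ writers emit nanometers and nanoseconds for readability, and
the readers convert back exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory_csv", "write_trajectory_csv",
           "write_trajectory_xyz"]

_NM = 1e-9
_NS = 1e-9


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled positions of one or more particles.

    Parameters
    ----------
    times : ndarray, shape (n_frames,)
        Strictly increasing sample times in seconds.
    positions : ndarray, shape (n_particles, n_frames, 3)
        Cartesian positions in meters.
    particle_ids : sequence of str, optional
        Labels, one per particle; defaults to ``p0, p1, ...``.
    """

    times: np.ndarray
    positions: np.ndarray
    particle_ids: tuple = field(default=None)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim == 2:  # single particle convenience
            positions = positions[None, :, :]
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_particles, n_frames, 3)")
        if times.ndim != 1 or times.size != positions.shape[1]:
            raise ValueError("times length must match the number of frames")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        ids = self.particle_ids
        if ids is None:
            ids = tuple(f"p{i}" for i in range(positions.shape[0]))
        else:
            ids = tuple(str(i) for i in ids)
            if len(ids) != positions.shape[0]:
                raise ValueError("one particle_id per particle required")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "particle_ids", ids)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in seconds; raises if sampling is not uniform."""
        steps = np.diff(self.times)
        if steps.size == 0:
            raise ValueError("trajectory has a single frame")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError(
                "non-uniform time spacing; resample the trajectory before "
                "MSD analysis")
        return float(steps[0])

    def rotated(self, rotation_matrix: np.ndarray) -> "Trajectory":
        """Rigidly rotate every position by a 3x3 rotation matrix."""
        R = np.asarray(rotation_matrix, dtype=float)
        return Trajectory(self.times, self.positions @ R.T, self.particle_ids)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write ``particle_id,time_ns,x_nm,y_nm,z_nm`` rows."""
    frames = []
    for p, pid in enumerate(traj.particle_ids):
        frames.append(pd.DataFrame({
            "particle_id": pid,
            "time_ns": traj.times / _NS,
            "x_nm": traj.positions[p, :, 0] / _NM,
            "y_nm": traj.positions[p, :, 1] / _NM,
            "z_nm": traj.positions[p, :, 2] / _NM,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_csv`.

    Every particle must report the identical frame grid; a missing frame is a
    parse error naming the particle and the time at which it was expected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"particle_id", "time_ns", "x_nm", "y_nm", "z_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    ids = list(dict.fromkeys(df["particle_id"].astype(str)))
    times_ns = np.unique(df["time_ns"].to_numpy(dtype=float))
    positions = np.empty((len(ids), times_ns.size, 3))
    for p, pid in enumerate(ids):
        sub = df[df["particle_id"].astype(str) == pid].sort_values("time_ns")
        t = sub["time_ns"].to_numpy(dtype=float)
        if t.size != times_ns.size or not np.array_equal(t, times_ns):
            lost = np.setdiff1d(times_ns, t)
            at = f"{lost[0]:g} ns" if lost.size else "a duplicated frame"
            raise ValueError(
                f"particle {pid!r}: missing frame at t = {at}")
        positions[p] = sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    return Trajectory(times_ns * _NS, positions * _NM, ids)


def write_trajectory_xyz(traj: Trajectory, path, comment: str = "") -> None:
    """Write frame blocks in plain XYZ format (coordinates in nm)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(f"t={traj.times[f] / _NS:.9g} ns {comment}\n")
            for p, pid in enumerate(traj.particle_ids):
                x, y, z = traj.positions[p, f] / _NM
                fh.write(f"{pid} {x:.9g} {y:.9g} {z:.9g}\n")
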