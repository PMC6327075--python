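"""Trajectory matrix extraction, life filtering, and kinematics.

The trajectory matrix is a trajectories x frames integer array whose entry
(t, n) is the vesicle index of trajectory t in frame n (0 = absent); each
row's non-zero entries form one contiguous block. The life of a trajectory
is its count of non-zero entries; a lower bound on life excludes
short-lived trajectories most likely born from image noise.

Kinematics per trajectory (positions x(n), inter-frame interval dt):

- velocity: forward difference at the first sample, central difference at
  interior samples, backward difference at the last;
- speed: the velocity magnitude;
- traveling distance s(n): cumulative path length, s(1) = 0;
- moving range R(n): running maximum displacement from the first position,
  R(1) = 0.

R(n) <= s(n) always, and both are non-decreasing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detection import DetectionSet
from .errors import IntegrityError, ParameterError, UndefinedVelocityError
from .trajectory import TRJ


class TrajectoryMatrix:
    """Rows = trajectories, columns = frames, entries = vesicle indices (0 = absent)."""

    def __init__(self, entries: np.ndarray, ids: np.ndarray | None = None):
        entries = np.asarray(entries, dtype=int)
        if entries.ndim != 2:
            raise IntegrityError(f"matrix must be 2-D, got shape {entries.shape}")
        self.entries = entries
        # original 1-based trajectory ids, preserved across life filtering
        self.ids = (
            np.arange(1, entries.shape[0] + 1) if ids is None else np.asarray(ids, dtype=int)
        )
        if self.ids.shape[0] != entries.shape[0]:
            raise IntegrityError("ids length does not match row count")

    @property
    def n_trajectories(self) -> int:
        return self.entries.shape[0]

    @property
    def n_frames(self) -> int:
        return self.entries.shape[1]

    @property
    def lives(self) -> np.ndarray:
        """Per-row count of non-zero entries."""
        return (self.entries != 0).sum(axis=1)

    def row_span(self, row: int) -> tuple[int, int]:
        """(first, last) 1-based frame indices of the row's non-zero block."""
        cols = np.nonzero(self.entries[row])[0]
        if cols.size == 0:
            raise IntegrityError(f"row {row} is empty")
        return int(cols[0] + 1), int(cols[-1] + 1)


def extract_matrix(trj: TRJ) -> TrajectoryMatrix:
    """Transcribe the TRJ store into a trajectory matrix (pid2 per frame)."""
    entries = np.zeros((trj.counter, trj.nframe), dtype=int)
    for tid in range(trj.counter):
        for iframe, _, pid2 in trj.dat[tid]:
            if entries[tid, iframe - 1] != 0:
                raise IntegrityError(
                    f"trajectory {tid + 1} assigned twice at frame {iframe}"
                )
            entries[tid, iframe - 1] = pid2
    return TrajectoryMatrix(entries)


def filter_by_life(M: TrajectoryMatrix, min_life: int) -> TrajectoryMatrix:
    """Drop rows with life < min_life, preserving row order and ids."""
    if min_life < 1:
        raise ParameterError(f"min_life must be >= 1, got {min_life}")
    keep = M.lives >= min_life
    return TrajectoryMatrix(M.entries[keep], M.ids[keep])


def velocity(positions: np.ndarray, dt: float) -> np.ndarray:
    """Per-sample velocity vectors from a coordinate sequence.

    Forward/central/backward differences at first/interior/last samples;
    output has the same length as the input.
    """
    positions = np.asarray(positions, dtype=float)
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    n = positions.shape[0]
    if n < 2:
        raise UndefinedVelocityError("velocity needs at least two samples")
    v = np.empty_like(positions)
    v[0] = (positions[1] - positions[0]) / dt
    v[-1] = (positions[-1] - positions[-2]) / dt
    if n > 2:
        v[1:-1] = (positions[2:] - positions[:-2]) / (2.0 * dt)
    return v


def speed(velocities: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of a velocity sequence."""
    return np.linalg.norm(np.asarray(velocities, dtype=float), axis=-1)


def traveling_distance(positions: np.ndarray) -> np.ndarray:
    """Cumulative path length s(n); s(1) = 0."""
    positions = np.asarray(positions, dtype=float)
    steps = np.linalg.norm(np.diff(positions, axis=0), axis=-1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def moving_range(positions: np.ndarray) -> np.ndarray:
    """Running maximum displacement from the first position; R(1) = 0."""
    positions = np.asarray(positions, dtype=float)
    disp = np.linalg.norm(positions - positions[0], axis=-1)
    out = np.maximum.accumulate(disp)
    out[0] = 0.0
    return out


def row_positions(
    M: TrajectoryMatrix, row: int, all_detections: list[DetectionSet]
) -> tuple[np.ndarray, np.ndarray]:
    """(frames, positions) for one matrix row's non-zero block."""
    cols = np.nonzero(M.entries[row])[0]
    frames = cols + 1
    pos = np.empty((cols.size, 2), dtype=float)
    for k, col in enumerate(cols):
        pid = int(M.entries[row, col])
        det = all_detections[col]
        if not 1 <= pid <= len(det):
            raise IntegrityError(f"vesicle {pid} missing in frame {col + 1}")
        pos[k] = det.positions[pid - 1]
    return frames, pos


def kinematics_table(
    M: TrajectoryMatrix,
    all_detections: list[DetectionSet],
    dt: float,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Per-sample kinematics for every matrix row.

    Columns: trajectory_id, frame, row, col, vx, vy, speed, s, R. Speeds
    are px/s, or scaled by ``pixel_size`` (length units per px) if given;
    life-1 trajectories get NaN velocities.
    """
    scale = 1.0 if pixel_size is None else float(pixel_size)
    chunks = []
    for r in range(M.n_trajectories):
        frames, pos = row_positions(M, r, all_detections)
        n = len(frames)
        if n >= 2:
            v = velocity(pos, dt) * scale
            sp = speed(v)
        else:
            v = np.full((n, 2), np.nan)
            sp = np.full(n, np.nan)
        chunks.append(
            pd.DataFrame(
                {
                    "trajectory_id": int(M.ids[r]),
                    "frame": frames,
                    "row": pos[:, 0],
                    "col": pos[:, 1],
                    "vx": v[:, 0],
                    "vy": v[:, 1],
                    "speed": sp,
                    "s": traveling_distance(pos) * scale,
                    "R": moving_range(pos) * scale,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["trajectory_id", "frame", "row", "col", "vx", "vy", "speed", "s", "R"]
        )
    return pd.concat(chunks, ignore_index=True)


def summarize(
    M: TrajectoryMatrix,
    all_detections: list[DetectionSet],
    dt: float,
    min_life: int = 1,
    pixel_size: float | None = None,
) -> pd.DataFrame:
    """Per-trajectory summary after life filtering.

    Columns: trajectory_id, life, mean_speed, final_range, final_distance.
    The surviving-trajectory count (the population) is stored in
    ``df.attrs["population"]``.
    """
    kept = filter_by_life(M, min_life)
    scale = 1.0 if pixel_size is None else float(pixel_size)
    rows = []
    for r in range(kept.n_trajectories):
        _, pos = row_positions(kept, r, all_detections)
        life = pos.shape[0]
        if life >= 2:
            mean_speed = float(np.mean(speed(velocity(pos, dt)))) * scale
        else:
            mean_speed = float("nan")
        rows.append(
            (
                int(kept.ids[r]),
                life,
                mean_speed,
                float(moving_range(pos)[-1]) * scale,
                float(traveling_distance(pos)[-1]) * scale,
            )
        )
    df = pd.DataFrame(
        rows, columns=["trajectory_id", "life", "mean_speed", "final_range", "final_distance"]
    )
    df.attrs["population"] = len(df)
    return df
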