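"""Reading, validating and writing optical-tracker pose trajectories.

A trajectory is a time-ordered sequence of 7-D tracker poses recorded by an
infrared stereo camera at a nominal 30 Hz: position x, y, z in millimetres in
the camera frame plus a scalar-first unit quaternion (q0, qx, qy, qz).
Orientation is validated and carried through I/O, but the predictor operates
on positions only — under ventilation the tracker's orientation is nearly
constant (quaternion component variation on the order of 0.02).

File format: plain CSV with a mandatory header ``t,x,y,z,q0,qx,qy,qz``
(seconds, millimetres, unitless), one row per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoseSample",
    "Trajectory",
    "TrajectoryFormatError",
    "TrajectoryValidationError",
    "read_trajectory",
    "write_trajectory",
    "positions_matrix",
]

COLUMNS = ("t", "x", "y", "z", "q0", "qx", "qy", "qz")

QUAT_NORM_TOL = 1e-3  # measurement tolerance on unit-quaternion norm


class TrajectoryFormatError(ValueError):
    """File does not have the expected columns/dialect."""


class TrajectoryValidationError(ValueError):
    """File parses but violates a trajectory invariant."""


@dataclass(frozen=True)
class PoseSample:
    """One tracker pose: time (s), position (mm), scalar-first quaternion."""

    t: float
    pos: np.ndarray  # shape (3,), mm
    quat: np.ndarray  # shape (4,), (q0, qx, qy, qz)

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos, dtype=float)
        quat = np.asarray(self.quat, dtype=float)
        if pos.shape != (3,):
            raise TrajectoryValidationError(f"pos must be a 3-vector, got {pos.shape}")
        if quat.shape != (4,):
            raise TrajectoryValidationError(f"quat must be a 4-vector, got {quat.shape}")
        if not np.all(np.isfinite(pos)):
            raise TrajectoryValidationError("position components must be finite")
        if not np.all(np.isfinite(quat)):
            raise TrajectoryValidationError("quaternion components must be finite")
        norm = float(np.linalg.norm(quat))
        if abs(norm - 1.0) > QUAT_NORM_TOL:
            raise TrajectoryValidationError(
                f"quaternion norm {norm:.6f} outside 1 ± {QUAT_NORM_TOL}"
            )
        object.__setattr__(self, "pos", pos)
        object.__setattr__(self, "quat", quat)


@dataclass(frozen=True)
class Trajectory:
    """Ordered pose samples with strictly increasing timestamps (length >= 2)."""

    samples: tuple[PoseSample, ...]
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        if len(samples) < 2:
            raise TrajectoryValidationError(
                f"trajectory needs at least 2 samples, got {len(samples)}"
            )
        times = np.array([s.t for s in samples])
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise TrajectoryValidationError(
                f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV, validating columns and invariants.

    Raises
    ------
    TrajectoryFormatError
        If the header is missing a required column or has extras.
    TrajectoryValidationError
        On NaNs, non-monotone timestamps (the error names the first offending
        0-based row index), bad quaternion norms, or fewer than 2 rows.
    """
    path = Path(path)
    # round_trip parsing: written floats must reload bit-identically
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise TrajectoryFormatError(f"unexpected column(s): {', '.join(extra)}")
    df = df[list(COLUMNS)]
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise TrajectoryValidationError(f"NaN field at row {row}")
    arr = df.to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(arr[:, 0]) <= 0)
    if bad.size:
        raise TrajectoryValidationError(
            f"timestamps not strictly increasing at row {int(bad[0]) + 1}"
        )
    samples = tuple(
        PoseSample(t=row[0], pos=row[1:4], quat=row[4:8]) for row in arr
    )
    return Trajectory(samples=samples)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV, re-readable by :func:`read_trajectory`."""
    rows = np.array(
        [[s.t, *s.pos, *s.quat] for s in traj.samples], dtype=float
    )
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    # 17 significant digits round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def positions_matrix(traj: Trajectory) -> np.ndarray:
    """Stack positions as a 3 x n matrix, one chronological column per sample."""
    return np.column_stack([s.pos for s in traj.samples])
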