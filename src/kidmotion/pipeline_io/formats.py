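"""Plain-text interchange formats for raw recordings and intermediates.

The device's native flash format is out of scope; the canonical dialect
is comma-delimited UTF-8 CSV with a header row, '.' decimal separator
and SI units (s, m, m/s^2).

IMU files:    t, ax, ay, az, gx, gy, gz, qw, qx, qy, qz, marker
              (gyroscope columns are carried but unused downstream;
              marker is 0/1, 1 flags an event sample)
optical files: t, x, y, z (empty cells mark occlusion gaps)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..datatypes import CycleSet, ImuRecording, MarkerTrajectory

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_mocap_csv",
    "write_mocap_csv",
    "read_cycles_csv",
    "write_cycles_csv",
]

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz", "marker"]
MOCAP_COLUMNS = ["t", "x", "y", "z"]

#: standard gravity for the optional G-to-SI conversion
STANDARD_G = 9.80665

_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def _read_table(path, columns: list[str], allow_nan: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    allow_nan = allow_nan or []
    for col in columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad.index[bad.isna() & df[col].notna()][0]) + 2
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}") from None
        if col not in allow_nan and df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3  # header + 1-based + next row
        raise ValueError(f"{path}: non-monotone timestamps at line {line}")
    return df


def _infer_fs(t: np.ndarray, declared: float | None) -> float:
    if declared is not None:
        return float(declared)
    if len(t) < 2:
        raise ValueError("cannot infer sampling rate from a single sample")
    return (len(t) - 1) / (t[-1] - t[0])


def read_imu_csv(
    path,
    fs: float | None = None,
    accel_in_g: bool = False,
    participant_id: str = "",
    movement_type=None,
) -> ImuRecording:
    """Read a raw IMU CSV.

    ``fs`` overrides the rate inferred from the timestamps (the declared
    rate wins on conflict).  ``accel_in_g`` converts accelerometer
    columns from G to m/s^2 (x 9.80665) on the way in.
    """
    df = _read_table(path, IMU_COLUMNS)
    t = df["t"].to_numpy(dtype=float)
    rate = _infer_fs(t, fs)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if accel_in_g:
        accel = accel * STANDARD_G
    markers = np.flatnonzero(df["marker"].to_numpy() != 0)
    return ImuRecording(
        timestamps=t,
        accel_device=accel,
        quaternion=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
        markers=markers,
        fs=rate,
        participant_id=participant_id,
        movement_type=movement_type,
    )


def write_imu_csv(rec: ImuRecording, path, gyro: np.ndarray | None = None) -> None:
    path = Path(path)
    n = len(rec)
    if gyro is None:
        gyro = np.zeros((n, 3))
    marker = np.zeros(n, dtype=int)
    marker[rec.markers] = 1
    df = pd.DataFrame(
        {
            "t": rec.timestamps,
            "ax": rec.accel_device[:, 0],
            "ay": rec.accel_device[:, 1],
            "az": rec.accel_device[:, 2],
            "gx": gyro[:, 0],
            "gy": gyro[:, 1],
            "gz": gyro[:, 2],
            "qw": rec.quaternion[:, 0],
            "qx": rec.quaternion[:, 1],
            "qy": rec.quaternion[:, 2],
            "qz": rec.quaternion[:, 3],
            "marker": marker,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_mocap_csv(path, fs: float | None = None) -> MarkerTrajectory:
    """Read an optical-marker CSV; empty position cells become NaN gaps."""
    df = _read_table(path, MOCAP_COLUMNS, allow_nan=["x", "y", "z"])
    t = df["t"].to_numpy(dtype=float)
    return MarkerTrajectory(
        timestamps=t,
        position=df[["x", "y", "z"]].to_numpy(dtype=float),
        fs=_infer_fs(t, fs),
    )


def write_mocap_csv(traj: MarkerTrajectory, path) -> None:
    df = pd.DataFrame(
        {
            "t": traj.timestamps,
            "x": traj.position[:, 0],
            "y": traj.position[:, 1],
            "z": traj.position[:, 2],
        }
    )
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_cycles_csv(cycles: CycleSet, path) -> None:
    """Serialize a cycle set as tidy CSV (one row per cycle x bin x channel)."""
    cycles.to_frame().to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_cycles_csv(path) -> CycleSet:
    df = pd.read_csv(Path(path))
    required = {"participant_id", "movement_type", "cycle_index", "source", "bin", "channel", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return CycleSet.from_frame(df)
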