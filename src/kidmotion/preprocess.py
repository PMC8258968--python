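"""Raw-stream conditioning: filtering, frame rotation, differentiation.

Both modalities end up as world-frame, gravity-free acceleration series
with the same axis semantics (x mediolateral, y anteroposterior,
z vertical), which is what makes them directly comparable downstream.

Processing-order choices (documented approximations):

* marker positions are low-pass filtered *before* double differentiation,
  because differentiation amplifies noise;
* IMU accelerations are rotated to the world frame sample-by-sample,
  gravity is removed, and only then is the result filtered.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .datatypes import ImuRecording, MarkerTrajectory, WorldAccelSeries

__all__ = [
    "lowpass_filter",
    "quat_to_rotation",
    "to_world_frame",
    "differentiate_position",
    "magnitude",
    "filter_series",
    "interpolate_gaps",
    "preprocess_imu",
    "preprocess_mocap",
]

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 2
MAX_GAP_SAMPLES = 10


def lowpass_filter(
    series: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    fs: float = 200.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    A 2nd-order design applied in both directions gives an effective
    4th-order, zero-lag response, the standard choice for kinematic data.
    Works on 1-D series or on ``(n, channels)`` arrays (filters along
    axis 0).
    """
    series = np.asarray(series, dtype=float)
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if fs <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff} Hz cutoff")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    min_len = 3 * (max(len(a), len(b)) - 1) + 1
    n = series.shape[0]
    if n < min_len:
        raise ValueError(f"series of length {n} too short to filter (need >= {min_len})")
    # generous odd-extension padding keeps startup transients out of the
    # data; essential when the result is differentiated afterwards
    padlen = min(int(round(3.0 * fs / cutoff)), n - 2)
    padlen = max(padlen, min_len - 1)
    return filtfilt(b, a, series, axis=0, padlen=padlen)


def quat_to_rotation(q) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion ``(w, x, y, z)``.

    The quaternion is renormalized if within 1e-3 of unit norm and
    rejected otherwise.  The returned matrix is a proper rotation
    (orthogonal, determinant +1) mapping device-frame vectors to the
    world frame.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError("quaternion must be a 4-vector (w, x, y, z)")
    norm = np.linalg.norm(q)
    if norm < 1e-12:
        raise ValueError("near-zero quaternion")
    if abs(norm - 1.0) > 1e-3:
        raise ValueError(f"quaternion norm {norm:.6f} deviates from 1 beyond tolerance")
    w, x, y, z = q / norm
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rotate_batch(quaternions: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Apply per-sample device-to-world rotations to per-sample vectors."""
    norms = np.linalg.norm(quaternions, axis=1, keepdims=True)
    q = quaternions / norms
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    vx, vy, vz = vectors[:, 0], vectors[:, 1], vectors[:, 2]
    out = np.empty_like(vectors)
    out[:, 0] = (
        (1 - 2 * (y * y + z * z)) * vx + 2 * (x * y - w * z) * vy + 2 * (x * z + w * y) * vz
    )
    out[:, 1] = (
        2 * (x * y + w * z) * vx + (1 - 2 * (x * x + z * z)) * vy + 2 * (y * z - w * x) * vz
    )
    out[:, 2] = (
        2 * (x * z - w * y) * vx + 2 * (y * z + w * x) * vy + (1 - 2 * (x * x + y * y)) * vz
    )
    return out


def to_world_frame(rec: ImuRecording, gravity: float = 9.81) -> WorldAccelSeries:
    """Rotate device accelerations into the world frame and remove gravity.

    A stationary accelerometer reads the upward reaction ``+gravity`` on
    the world z axis, so that constant is subtracted after rotation; what
    remains is motion acceleration only.  Pass ``gravity=0`` to disable
    the subtraction.
    """
    world = _rotate_batch(rec.quaternion, rec.accel_device)
    world[:, 2] -= gravity
    return WorldAccelSeries.from_components(
        world[:, 0], world[:, 1], world[:, 2], fs=rec.fs, source="kid"
    )


def differentiate_position(traj: MarkerTrajectory) -> WorldAccelSeries:
    """Acceleration as the second derivative of marker position.

    Interior samples use the central second difference
    ``(p[i+1] - 2 p[i] + p[i-1]) * fs**2`` (exact for quadratics); the two
    endpoints reuse their neighbouring one-sided estimate.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples to differentiate twice")
    p = traj.position
    acc = np.empty_like(p)
    acc[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) * traj.fs**2
    acc[0] = (p[2] - 2.0 * p[1] + p[0]) * traj.fs**2
    acc[-1] = (p[-1] - 2.0 * p[-2] + p[-3]) * traj.fs**2
    return WorldAccelSeries.from_components(
        acc[:, 0], acc[:, 1], acc[:, 2], fs=traj.fs, source="mocap"
    )


def magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm of the three axis series."""
    ax, ay, az = (np.asarray(c, dtype=float) for c in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("channel lengths differ")
    return np.sqrt(ax**2 + ay**2 + az**2)


def filter_series(
    series: WorldAccelSeries,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> WorldAccelSeries:
    """Low-pass each axis channel, then recompute the magnitude."""
    ax = lowpass_filter(series.ax, cutoff, series.fs, order)
    ay = lowpass_filter(series.ay, cutoff, series.fs, order)
    az = lowpass_filter(series.az, cutoff, series.fs, order)
    return WorldAccelSeries.from_components(ax, ay, az, fs=series.fs, source=series.source)


def interpolate_gaps(traj: MarkerTrajectory, max_gap: int = MAX_GAP_SAMPLES) -> MarkerTrajectory:
    """Linearly interpolate NaN gaps of at most ``max_gap`` samples."""
    p = traj.position.copy()
    bad = ~np.isfinite(p).all(axis=1)
    if not bad.any():
        return traj
    # locate runs of consecutive bad samples
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start > max_gap:
            raise ValueError(f"marker gap of {stop - start} samples exceeds {max_gap}")
        if start == 0 or stop == len(p):
            raise ValueError("cannot interpolate a gap at the series edge")
        for c in range(3):
            p[start:stop, c] = np.interp(
                np.arange(start, stop), [start - 1, stop], [p[start - 1, c], p[stop, c]]
            )
    return MarkerTrajectory(timestamps=traj.timestamps, position=p, fs=traj.fs)


def preprocess_imu(
    rec: ImuRecording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    gravity: float = 9.81,
) -> WorldAccelSeries:
    """Full IMU chain: rotate to world, remove gravity, low-pass, magnitude."""
    return filter_series(to_world_frame(rec, gravity=gravity), cutoff=cutoff, order=order)


def preprocess_mocap(
    traj: MarkerTrajectory,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> WorldAccelSeries:
    """Full optical chain: fill gaps, low-pass positions, differentiate twice."""
    traj = interpolate_gaps(traj)
    filtered = lowpass_filter(traj.position, cutoff, traj.fs, order)
    smooth = MarkerTrajectory(timestamps=traj.timestamps, position=filtered, fs=traj.fs)
    return differentiate_position(smooth)
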