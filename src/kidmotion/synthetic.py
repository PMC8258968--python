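"""Closed-form simulator of paired marker-trajectory / IMU recordings.

The simulator produces the statistical structure the downstream analysis
assumes: sinusoidal limb trajectories sampled at a fixed rate, optical
positions with additive Gaussian noise, and a device-frame accelerometer
stream that contains gravity, is expressed in an arbitrary (but known)
sensor orientation, carries its own noise, and lags the optical stream
by an unknown integer number of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    ImuRecording,
    MarkerTrajectory,
    MovementSpec,
    MovementType,
    SimulationConfig,
)
from .preprocess import quat_to_rotation

__all__ = [
    "SyntheticTrajectory",
    "DatasetRecord",
    "SyntheticDataset",
    "generate_trajectory",
    "simulate_imu",
    "generate_dataset",
    "default_movement_specs",
]

#: resting world position of the wrist (m); constant offsets are inert
_REST_POSITION = np.array([0.0, 0.30, 1.0])

#: injected lag is drawn from [0, _MAX_INJECTED_LAG_S * fs] per recording
_MAX_INJECTED_LAG_S = 0.5


@dataclass
class SyntheticTrajectory:
    """A noisy marker trajectory plus its analytic ground truth."""

    trajectory: MarkerTrajectory
    boundaries: np.ndarray  # n_cycles + 1 sample indices, last == len(trajectory)
    position_clean: np.ndarray
    world_accel: np.ndarray  # analytic motion acceleration, gravity-free

    def __iter__(self):
        # allow ``traj, boundaries = generate_trajectory(...)`` unpacking
        return iter((self.trajectory, self.boundaries))


def _cycle_boundaries(spec: MovementSpec, fs: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Sample indices of cycle starts (plus the end of the last cycle)."""
    durations = np.full(spec.n_cycles, spec.cycle_duration)
    if jitter > 0:
        durations = durations * (1.0 + rng.uniform(-jitter, jitter, size=spec.n_cycles))
    edges_t = np.concatenate([[0.0], np.cumsum(durations)])
    boundaries = np.rint(edges_t * fs).astype(np.intp)
    if np.any(np.diff(boundaries) < 2):
        raise ValueError("cycle_duration too short for the sampling rate")
    return boundaries


def _phase(boundaries: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample phase (2*pi per cycle) and angular rate d(phase)/dt."""
    n = int(boundaries[-1])
    theta = np.empty(n)
    omega = np.empty(n)
    for k in range(len(boundaries) - 1):
        lo, hi = int(boundaries[k]), int(boundaries[k + 1])
        frac = np.arange(lo, hi) - lo
        theta[lo:hi] = 2.0 * np.pi * (k + frac / (hi - lo))
        omega[lo:hi] = 2.0 * np.pi * fs / (hi - lo)
    return theta, omega


def _curve(spec: MovementSpec, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Position offset and its second derivative w.r.t. phase, shape (n, 3)."""
    n = len(theta)
    pos = np.zeros((n, 3))
    d2 = np.zeros((n, 3))
    mt = spec.movement_type
    if mt is MovementType.HORIZONTAL:
        half = spec.extent / 2.0
        pos[:, 0] = half * np.sin(theta)
        d2[:, 0] = -half * np.sin(theta)
    elif mt is MovementType.VERTICAL:
        half = spec.extent / 2.0
        pos[:, 2] = half * np.sin(theta)
        d2[:, 2] = -half * np.sin(theta)
    elif mt is MovementType.ELLIPTICAL:
        a, b = spec.semi_axes
        pos[:, 0] = a * np.cos(theta)
        pos[:, 2] = b * np.sin(theta)
        d2[:, 0] = -a * np.cos(theta)
        d2[:, 2] = -b * np.sin(theta)
    elif mt is MovementType.FIGURE_EIGHT:
        # 1:2 Lissajous traces the standard analytic figure-eight
        a, b = spec.semi_axes
        pos[:, 0] = a * np.sin(theta)
        pos[:, 2] = b * np.sin(2.0 * theta)
        d2[:, 0] = -a * np.sin(theta)
        d2[:, 2] = -4.0 * b * np.sin(2.0 * theta)
    else:  # pragma: no cover
        raise ValueError(f"unknown movement type {mt}")
    return pos, d2


def generate_trajectory(
    spec: MovementSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticTrajectory:
    """Sample a closed-form cyclic trajectory at ``cfg.sampling_rate``.

    Returns the noisy :class:`MarkerTrajectory` together with ground-truth
    cycle boundary indices (``n_cycles + 1`` of them; the last one equals
    the series length) and the analytic, gravity-free world acceleration.
    Per-cycle duration jitter (``cfg.cycle_jitter``) stretches each cycle
    independently; with zero jitter the boundaries fall at exact integer
    multiples of the cycle duration.
    """
    if rng is None:
        rng = cfg.rng()
    fs = cfg.sampling_rate
    boundaries = _cycle_boundaries(spec, fs, cfg.cycle_jitter, rng)
    theta, omega = _phase(boundaries, fs)
    pos_offset, d2 = _curve(spec, theta)
    position_clean = _REST_POSITION + pos_offset
    world_accel = d2 * omega[:, None] ** 2
    position = position_clean.copy()
    if cfg.position_noise_sd > 0:
        position = position + rng.normal(0.0, cfg.position_noise_sd, size=position.shape)
    n = len(position)
    traj = MarkerTrajectory(timestamps=np.arange(n) / fs, position=position, fs=fs)
    return SyntheticTrajectory(
        trajectory=traj,
        boundaries=boundaries,
        position_clean=position_clean,
        world_accel=world_accel,
    )


def _second_difference(position: np.ndarray, fs: float) -> np.ndarray:
    acc = np.empty_like(position)
    acc[1:-1] = (position[2:] - 2.0 * position[1:-1] + position[:-2]) * fs**2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def simulate_imu(
    traj: SyntheticTrajectory | MarkerTrajectory,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    boundaries: np.ndarray | None = None,
    world_accel: np.ndarray | None = None,
    participant_id: str = "",
    movement_type: MovementType | None = None,
) -> ImuRecording:
    """Render an IMU stream for a trajectory.

    The accelerometer reads specific force: motion acceleration plus the
    upward reaction to gravity (``+cfg.gravity`` on world z when at rest),
    rotated into the device frame by the inverse of the device-to-world
    orientation quaternion.  The stream is delayed by ``cfg.lag_samples``
    rest-pose samples, padded with ``cfg.tail_samples`` rest-pose samples
    at the end, and carries Gaussian noise of SD ``cfg.accel_noise_sd``.
    Event markers are emitted at the true cycle boundaries.
    """
    if isinstance(traj, SyntheticTrajectory):
        if boundaries is None:
            boundaries = traj.boundaries
        if world_accel is None:
            world_accel = traj.world_accel
        traj = traj.trajectory
    if rng is None:
        rng = cfg.rng()
    if world_accel is None:
        world_accel = _second_difference(traj.position, traj.fs)
    world_accel = np.asarray(world_accel, dtype=float)

    rot = quat_to_rotation(cfg.device_orientation)  # device -> world
    g_world = np.array([0.0, 0.0, cfg.gravity])
    f_world = world_accel + g_world
    f_device = f_world @ rot  # row-wise R.T @ f
    rest_device = rot.T @ g_world

    lag, tail = cfg.lag_samples, cfg.tail_samples
    n = len(f_device)
    accel = np.vstack(
        [
            np.tile(rest_device, (lag, 1)),
            f_device,
            np.tile(rest_device, (tail, 1)),
        ]
    )
    if cfg.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, cfg.accel_noise_sd, size=accel.shape)

    total = lag + n + tail
    quat = np.tile(np.asarray(cfg.device_orientation, dtype=float), (total, 1))
    markers = np.array([], dtype=np.intp)
    if boundaries is not None:
        markers = np.asarray(boundaries, dtype=np.intp) + lag
        if markers.size and markers[-1] >= total:
            warnings.warn(
                "final cycle marker falls past the end of the recording and is dropped; "
                "set tail_samples >= 1 to keep it",
                stacklevel=2,
            )
            markers = markers[markers < total]
    return ImuRecording(
        timestamps=np.arange(total) / traj.fs,
        accel_device=accel,
        quaternion=quat,
        markers=markers,
        fs=traj.fs,
        participant_id=participant_id,
        movement_type=movement_type,
    )


def default_movement_specs(cycle_duration: float = 2.0, n_cycles: int = 10) -> list[MovementSpec]:
    """One spec per movement type with the protocol's default geometry."""
    return [
        MovementSpec(mt, cycle_duration=cycle_duration, n_cycles=n_cycles)
        for mt in MovementType
    ]


@dataclass
class DatasetRecord:
    """One participant x movement-type paired recording with ground truth."""

    participant_id: str
    movement_type: MovementType
    imu: ImuRecording
    mocap: MarkerTrajectory
    boundaries: np.ndarray  # cycle boundaries on the marker-stream timeline
    lag: int
    orientation: tuple[float, float, float, float]
    world_accel_truth: np.ndarray = field(repr=False, default=None)


@dataclass
class SyntheticDataset:
    records: list[DatasetRecord]
    cfg: SimulationConfig

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def generate_dataset(
    n_participants: int,
    movement_specs: list[MovementSpec] | None = None,
    cfg: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Generate the full paired study design.

    Each participant gets a randomized (constant) device orientation, an
    independent integer stream lag, and per-cycle duration jitter; all
    randomness derives from ``cfg.seed``, so identical seeds reproduce the
    dataset exactly.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if movement_specs is None:
        movement_specs = default_movement_specs()
    if cfg is None:
        cfg = SimulationConfig(seed=0)
    rng = cfg.rng()
    max_lag = int(round(_MAX_INJECTED_LAG_S * cfg.sampling_rate))
    width = max(2, len(str(n_participants)))
    records: list[DatasetRecord] = []
    for p in range(n_participants):
        pid = f"p{p + 1:0{width}d}"
        q = rng.normal(size=4)
        q = tuple(q / np.linalg.norm(q))
        for spec in movement_specs:
            lag = int(rng.integers(0, max_lag + 1))
            rec_cfg = replace(cfg, device_orientation=q, lag_samples=lag)
            sim = generate_trajectory(spec, rec_cfg, rng)
            imu = simulate_imu(
                sim,
                rec_cfg,
                rng,
                participant_id=pid,
                movement_type=spec.movement_type,
            )
            records.append(
                DatasetRecord(
                    participant_id=pid,
                    movement_type=spec.movement_type,
                    imu=imu,
                    mocap=sim.trajectory,
                    boundaries=sim.boundaries,
                    lag=lag,
                    orientation=q,
                    world_accel_truth=sim.world_accel,
                )
            )
    return SyntheticDataset(records=records, cfg=cfg)
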