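"""Filtering, rotation and differentiation tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from kidmotion.datatypes import (
    ImuRecording,
    MarkerTrajectory,
    MovementSpec,
    MovementType,
    SimulationConfig,
)
from kidmotion.preprocess import (
    differentiate_position,
    filter_series,
    interpolate_gaps,
    lowpass_filter,
    magnitude,
    preprocess_imu,
    quat_to_rotation,
    to_world_frame,
)
from kidmotion.synthetic import generate_trajectory, simulate_imu

FS = 200.0


def _sine(freq: float, n: int = 4000, fs: float = FS) -> np.ndarray:
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _amplitude(x: np.ndarray, freq: float, fs: float = FS) -> float:
    """Least-squares amplitude of a known-frequency sinusoid."""
    t = np.arange(len(x)) / fs
    basis = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return float(np.hypot(*coef))


class TestLowpassFilter:
    def test_dc_passband(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 6.0, FS), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        x = _sine(1.0)
        y = lowpass_filter(x, 6.0, FS)
        assert _amplitude(y, 1.0) == pytest.approx(1.0, abs=0.01)

    def test_stopband_sinusoid_suppressed(self):
        # analytic two-pass magnitude: (1 + (50/6)^4)^-1 ~ 2e-4
        x = _sine(50.0)
        y = lowpass_filter(x, 6.0, FS)
        assert _amplitude(y, 50.0) < 1e-3

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_filter(np.ones(5), 6.0, FS)

    def test_nyquist_violation_errors(self):
        with pytest.raises(ValueError, match="too low"):
            lowpass_filter(np.ones(100), 6.0, 10.0)

    def test_multichannel(self):
        x = np.column_stack([_sine(1.0), np.full(4000, 2.0)])
        y = lowpass_filter(x, 6.0, FS)
        assert y.shape == x.shape
        np.testing.assert_allclose(y[:, 1], 2.0, atol=1e-9)


class TestQuatToRotation:
    def test_identity(self):
        np.testing.assert_allclose(quat_to_rotation([1, 0, 0, 0]), np.eye(3), atol=1e-15)

    def test_90deg_about_z(self):
        s = np.sqrt(2) / 2
        rot = quat_to_rotation([s, 0, 0, s])
        np.testing.assert_allclose(rot @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_near_zero_rejected(self):
        with pytest.raises(ValueError, match="near-zero"):
            quat_to_rotation([1e-13, 0, 0, 0])

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="deviates"):
            quat_to_rotation([1.1, 0, 0, 0])

    @given(st.lists(st.floats(-1, 1), min_size=4, max_size=4).filter(lambda q: np.linalg.norm(q) > 0.1))
    @settings(max_examples=50, deadline=None)
    def test_proper_rotation_properties(self, q):
        q = np.asarray(q) / np.linalg.norm(q)
        rot = quat_to_rotation(q)
        np.testing.assert_allclose(rot.T @ rot, np.eye(3), atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    @given(st.lists(st.floats(-1, 1), min_size=4, max_size=4).filter(lambda q: np.linalg.norm(q) > 0.1))
    @settings(max_examples=25, deadline=None)
    def test_matches_scipy(self, q):
        q = np.asarray(q) / np.linalg.norm(q)
        ours = quat_to_rotation(q)
        theirs = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()  # xyzw
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


def _static_recording(q, accel, n=50):
    return ImuRecording(
        timestamps=np.arange(n) / FS,
        accel_device=np.tile(accel, (n, 1)),
        quaternion=np.tile(q, (n, 1)),
        markers=[],
        fs=FS,
    )


class TestToWorldFrame:
    def test_stationary_any_orientation(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        rot = quat_to_rotation(q)
        device_gravity = rot.T @ [0, 0, 9.81]
        world = to_world_frame(_static_recording(q, device_gravity))
        assert np.abs(world.stacked()[:, :3]).max() < 1e-9

    def test_identity_orientation_arithmetic(self):
        world = to_world_frame(_static_recording([1, 0, 0, 0], [0.0, 0.0, 9.81 + 2.0]))
        np.testing.assert_allclose(world.az, 2.0, atol=1e-12)
        np.testing.assert_allclose(world.ax, 0.0, atol=1e-12)

    def test_simulator_round_trip_zero_noise(self):
        cfg = SimulationConfig(
            accel_noise_sd=0.0,
            position_noise_sd=0.0,
            cycle_jitter=0.0,
            device_orientation=(0.5, 0.5, 0.5, 0.5),
            seed=0,
        )
        sim = generate_trajectory(MovementSpec(MovementType.FIGURE_EIGHT, n_cycles=2), cfg)
        imu = simulate_imu(sim, cfg)
        world = to_world_frame(imu, gravity=cfg.gravity)
        n = len(sim.world_accel)
        assert np.abs(world.stacked()[:n, :3] - sim.world_accel).max() < 1e-9

    def test_orientation_invariance(self):
        clean = dict(accel_noise_sd=0.0, position_noise_sd=0.0, cycle_jitter=0.0, seed=0)
        spec = MovementSpec(MovementType.ELLIPTICAL, n_cycles=2)
        results = []
        for q in [(1, 0, 0, 0), (0.5, 0.5, 0.5, 0.5)]:
            cfg = SimulationConfig(**clean, device_orientation=q)
            sim = generate_trajectory(spec, cfg)
            world = to_world_frame(simulate_imu(sim, cfg), gravity=cfg.gravity)
            results.append(world.stacked())
        assert np.abs(results[0] - results[1]).max() < 1e-6


class TestDifferentiatePosition:
    def _traj(self, p):
        return MarkerTrajectory(timestamps=np.arange(len(p)) / FS, position=p, fs=FS)

    def test_linear_ramp_zero_accel(self):
        t = np.arange(100) / FS
        p = np.column_stack([t, 2 * t, -t])
        acc = differentiate_position(self._traj(p))
        assert np.abs(acc.stacked()[1:-1, :3]).max() < 1e-9

    def test_sine_matches_closed_form(self):
        f = 0.5
        t = np.arange(4000) / FS
        p = np.column_stack([np.sin(2 * np.pi * f * t), np.zeros_like(t), np.zeros_like(t)])
        acc = differentiate_position(self._traj(p))
        expected = -((2 * np.pi * f) ** 2) * np.sin(2 * np.pi * f * t)
        interior = slice(1, -1)
        max_err = np.abs(acc.ax[interior] - expected[interior]).max()
        assert max_err < 1e-3 * (2 * np.pi * f) ** 2

    def test_quadratic_exact(self):
        c = 3.0
        t = np.arange(200) / FS
        p = np.column_stack([0.5 * c * t**2, np.zeros_like(t), np.zeros_like(t)])
        acc = differentiate_position(self._traj(p))
        np.testing.assert_allclose(acc.ax[1:-1], c, rtol=1e-9)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            differentiate_position(self._traj(np.zeros((2, 3))))


class TestMagnitude:
    def test_three_four_five(self):
        assert magnitude([3.0], [4.0], [0.0])[0] == pytest.approx(5.0)

    def test_zeros(self):
        np.testing.assert_array_equal(magnitude(np.zeros(5), np.zeros(5), np.zeros(5)), np.zeros(5))

    def test_sqrt3(self):
        assert magnitude([1.0], [1.0], [1.0])[0] == pytest.approx(np.sqrt(3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            magnitude([1.0, 2.0], [1.0], [1.0])


class TestGapHandling:
    def test_short_gap_interpolated(self):
        p = np.tile(np.linspace(0, 1, 50)[:, None], (1, 3))
        p[10:13] = np.nan
        traj = MarkerTrajectory(timestamps=np.arange(50) / FS, position=p, fs=FS)
        fixed = interpolate_gaps(traj)
        assert np.isfinite(fixed.position).all()
        np.testing.assert_allclose(fixed.position[:, 0], np.linspace(0, 1, 50), atol=1e-12)

    def test_long_gap_rejected(self):
        p = np.ones((50, 3))
        p[10:25] = np.nan
        traj = MarkerTrajectory(timestamps=np.arange(50) / FS, position=p, fs=FS)
        with pytest.raises(ValueError, match="exceeds"):
            interpolate_gaps(traj)


def test_filter_then_differentiate_recovers_analytic_accel():
    """<= 1 Hz content survives the 6 Hz chain within 1% RMS."""
    from kidmotion.preprocess import preprocess_mocap

    cfg = SimulationConfig(accel_noise_sd=0.0, position_noise_sd=0.0, cycle_jitter=0.0, seed=0)
    spec = MovementSpec(MovementType.VERTICAL, cycle_duration=2.0, n_cycles=10)
    sim = generate_trajectory(spec, cfg)
    acc = preprocess_mocap(sim.trajectory)
    truth = sim.world_accel[:, 2]
    rms_err = np.sqrt(np.mean((acc.az - truth) ** 2))
    rms_sig = np.sqrt(np.mean(truth**2))
    assert rms_err < 0.01 * rms_sig


def test_preprocess_imu_smoke():
    cfg = SimulationConfig(seed=0)
    sim = generate_trajectory(MovementSpec(MovementType.HORIZONTAL, n_cycles=2), cfg)
    world = preprocess_imu(simulate_imu(sim, cfg))
    assert len(world) == len(sim.trajectory) + cfg.tail_samples + cfg.lag_samples
    np.testing.assert_allclose(world.am, magnitude(world.ax, world.ay, world.az))
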