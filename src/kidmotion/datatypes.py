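"""Core data containers shared by all pipeline stages.

Conventions fixed here once and relied on everywhere else:

* world frame: x = mediolateral (left-right), y = anteroposterior,
  z = vertical; gravity acts along -z.
* quaternions are Hamilton, scalar-first ``(w, x, y, z)``, unit norm,
  and encode the device-to-world rotation.
* acceleration channels are ordered ``(ax, ay, az, am)`` wherever they
  are stacked into a single array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MovementType",
    "MovementSpec",
    "SimulationConfig",
    "ImuRecording",
    "MarkerTrajectory",
    "WorldAccelSeries",
    "CycleSet",
    "MeanSquares",
    "IccResult",
    "FeatureTable",
    "ClassificationResult",
    "CHANNELS",
]

#: channel order used in every stacked acceleration array
CHANNELS = ("ax", "ay", "az", "am")

#: quaternion norm tolerance: renormalize within this, reject beyond
QUAT_NORM_TOL = 1e-3


class MovementType(str, Enum):
    """The four cyclic arm-movement shapes."""

    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"
    ELLIPTICAL = "elliptical"
    FIGURE_EIGHT = "figure_eight"


# default geometry (meters): peak-to-peak extents for the 1-D movements,
# semi-axes for the planar shapes (major 22.5 cm, minor 15.1 cm)
_DEFAULT_EXTENT = {
    MovementType.HORIZONTAL: 0.40,
    MovementType.VERTICAL: 0.50,
}
_DEFAULT_SEMI_AXES = (0.1125, 0.0755)


@dataclass(frozen=True)
class MovementSpec:
    """Geometry and cadence of one cyclic movement series.

    Parameters
    ----------
    movement_type
        One of the four shapes.
    cycle_duration
        Nominal duration of one cycle in seconds (tempo is a free
        parameter of the protocol, default 2 s).
    n_cycles
        Number of repetitions.
    extent
        Peak-to-peak excursion in meters for ``horizontal`` /
        ``vertical``; defaults to 0.40 / 0.50 m.
    semi_axes
        ``(a, b)`` semi-axes in meters for ``elliptical`` /
        ``figure_eight``; defaults to (0.1125, 0.0755).
    """

    movement_type: MovementType
    cycle_duration: float = 2.0
    n_cycles: int = 10
    extent: float | None = None
    semi_axes: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        mt = MovementType(self.movement_type)
        object.__setattr__(self, "movement_type", mt)
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if mt in _DEFAULT_EXTENT:
            extent = self.extent if self.extent is not None else _DEFAULT_EXTENT[mt]
            if extent <= 0:
                raise ValueError("extent must be > 0")
            object.__setattr__(self, "extent", float(extent))
        else:
            axes = self.semi_axes if self.semi_axes is not None else _DEFAULT_SEMI_AXES
            a, b = (float(axes[0]), float(axes[1]))
            if a <= 0 or b <= 0:
                raise ValueError("semi_axes must be > 0")
            object.__setattr__(self, "semi_axes", (a, b))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the paired-stream simulator.

    ``device_orientation`` is the (constant) device-to-world quaternion;
    ``lag_samples`` delays the IMU stream relative to the marker stream
    by prepending rest-pose samples; ``tail_samples`` appends rest-pose
    samples after the last cycle so that the final cycle marker falls on
    a recorded sample.  ``cycle_jitter`` is the half-width of the
    uniform per-cycle duration perturbation (fraction of the nominal
    duration).
    """

    sampling_rate: float = 200.0
    accel_noise_sd: float = 0.05
    position_noise_sd: float = 0.0005
    device_orientation: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    lag_samples: int = 0
    tail_samples: int = 10
    gravity: float = 9.81
    cycle_jitter: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.accel_noise_sd < 0 or self.position_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.lag_samples < 0:
            raise ValueError("lag_samples must be >= 0")
        if self.tail_samples < 0:
            raise ValueError("tail_samples must be >= 0")
        if not 0 <= self.cycle_jitter < 1:
            raise ValueError("cycle_jitter must be in [0, 1)")
        q = np.asarray(self.device_orientation, dtype=float)
        if q.shape != (4,):
            raise ValueError("device_orientation must be a 4-vector (w, x, y, z)")
        norm = float(np.linalg.norm(q))
        if abs(norm - 1.0) > QUAT_NORM_TOL:
            raise ValueError(f"device_orientation is not a unit quaternion (|q| = {norm:.6f})")
        object.__setattr__(self, "device_orientation", tuple(q / norm))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _as_float_array(x, name: str, ndim: int, width: int | None = None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional")
    if width is not None and arr.shape[1] != width:
        raise ValueError(f"{name} must have {width} columns")
    return arr


def _check_uniform(timestamps: np.ndarray, fs: float) -> None:
    if len(timestamps) > 1:
        dt = np.diff(timestamps)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.allclose(dt, 1.0 / fs, atol=1e-6 / fs):
            raise ValueError("timestamps must be uniform at the declared rate")


@dataclass
class ImuRecording:
    """Raw device-frame recording: acceleration, orientation, event markers."""

    timestamps: np.ndarray
    accel_device: np.ndarray
    quaternion: np.ndarray
    markers: np.ndarray
    fs: float
    participant_id: str = ""
    movement_type: MovementType | None = None

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.accel_device = _as_float_array(self.accel_device, "accel_device", 2, 3)
        self.quaternion = _as_float_array(self.quaternion, "quaternion", 2, 4)
        self.markers = np.asarray(self.markers, dtype=np.intp)
        n = len(self.timestamps)
        if len(self.accel_device) != n or len(self.quaternion) != n:
            raise ValueError("timestamps, accel_device and quaternion lengths differ")
        _check_uniform(self.timestamps, self.fs)
        norms = np.linalg.norm(self.quaternion, axis=1)
        if np.any(np.abs(norms - 1.0) > QUAT_NORM_TOL):
            raise ValueError("quaternions deviate from unit norm beyond tolerance")
        self.quaternion = self.quaternion / norms[:, None]
        if self.markers.size:
            if np.any(np.diff(self.markers) <= 0):
                raise ValueError("markers must be strictly increasing")
            if self.markers[0] < 0 or self.markers[-1] >= n:
                raise ValueError("markers out of range")
        if self.movement_type is not None:
            self.movement_type = MovementType(self.movement_type)

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class MarkerTrajectory:
    """3-D position time series of a single retroreflective marker."""

    timestamps: np.ndarray
    position: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.timestamps = _as_float_array(self.timestamps, "timestamps", 1)
        self.position = _as_float_array(self.position, "position", 2, 3)
        if len(self.timestamps) != len(self.position):
            raise ValueError("timestamps and position lengths differ")
        _check_uniform(self.timestamps, self.fs)

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class WorldAccelSeries:
    """World-frame, gravity-free acceleration channels plus magnitude."""

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    am: np.ndarray
    fs: float
    source: str = "kid"

    def __post_init__(self) -> None:
        for name in ("ax", "ay", "az", "am"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.ax)
        if not (len(self.ay) == len(self.az) == len(self.am) == n):
            raise ValueError("channel lengths differ")
        if self.source not in ("kid", "mocap"):
            raise ValueError("source must be 'kid' or 'mocap'")

    @classmethod
    def from_components(
        cls, ax: np.ndarray, ay: np.ndarray, az: np.ndarray, fs: float, source: str = "kid"
    ) -> "WorldAccelSeries":
        ax, ay, az = (np.asarray(c, dtype=float) for c in (ax, ay, az))
        am = np.sqrt(ax**2 + ay**2 + az**2)
        return cls(ax=ax, ay=ay, az=az, am=am, fs=fs, source=source)

    def stacked(self) -> np.ndarray:
        """Return an ``(n, 4)`` array in channel order (ax, ay, az, am)."""
        return np.column_stack([self.ax, self.ay, self.az, self.am])

    def sliced(self, start: int, stop: int) -> "WorldAccelSeries":
        return WorldAccelSeries(
            ax=self.ax[start:stop],
            ay=self.ay[start:stop],
            az=self.az[start:stop],
            am=self.am[start:stop],
            fs=self.fs,
            source=self.source,
        )

    def __len__(self) -> int:
        return len(self.ax)


@dataclass
class CycleSet:
    """Segmented, time-normalized cycles: ``data[cycle, bin, channel]``.

    ``labels`` has one row per cycle with columns ``participant_id``,
    ``movement_type``, ``cycle_index`` and ``source``.  Note that the
    ``am`` channel equals the norm of the other three only at raw-sample
    level; within-bin averaging does not commute with the norm.
    """

    data: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(CHANNELS):
            raise ValueError("data must be (cycle, bin, channel) with 4 channels")
        required = {"participant_id", "movement_type", "cycle_index", "source"}
        missing = required - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels and data row counts differ")

    @property
    def n_cycles(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return ``data[:, :, i]`` for channel ``name``."""
        return self.data[:, :, CHANNELS.index(name)]

    @staticmethod
    def concatenate(parts: Sequence["CycleSet"]) -> "CycleSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        bins = {p.n_bins for p in parts}
        if len(bins) != 1:
            raise ValueError("bin counts differ across parts")
        data = np.concatenate([p.data for p in parts], axis=0)
        labels = pd.concat([p.labels for p in parts], ignore_index=True)
        return CycleSet(data=data, labels=labels)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per cycle x bin x channel."""
        n_c, n_b, n_ch = self.data.shape
        idx = np.repeat(np.arange(n_c), n_b * n_ch)
        rows = self.labels.iloc[idx].reset_index(drop=True)
        rows["bin"] = np.tile(np.repeat(np.arange(n_b), n_ch), n_c)
        rows["channel"] = np.tile(np.array(CHANNELS), n_c * n_b)
        rows["value"] = self.data.ravel()
        return rows

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CycleSet":
        n_b = int(frame["bin"].max()) + 1
        n_ch = len(CHANNELS)
        label_cols = ["participant_id", "movement_type", "cycle_index", "source"]
        rows_per_cycle = n_b * n_ch
        if len(frame) % rows_per_cycle:
            raise ValueError("frame length is not a multiple of bins x channels")
        n_c = len(frame) // rows_per_cycle
        data = frame["value"].to_numpy(dtype=float).reshape(n_c, n_b, n_ch)
        labels = frame[label_cols].iloc[::rows_per_cycle].reset_index(drop=True)
        return cls(data=data, labels=labels)


@dataclass(frozen=True)
class MeanSquares:
    """Two-way crossed ANOVA mean squares for an ``n x k`` table."""

    msr: float
    msc: float
    mse: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.n < 2 or self.k < 2:
            raise ValueError("need n >= 2 rows and k >= 2 columns")
        if min(self.msr, self.msc, self.mse) < -1e-12:
            raise ValueError("mean squares must be non-negative")

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)


@dataclass(frozen=True)
class IccTest:
    """F-test of an intraclass correlation against zero."""

    F: float
    df1: float
    df2: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class IccResult:
    movement_type: str
    consistency: float
    absolute_agreement: float
    consistency_test: IccTest
    agreement_test: IccTest
    p_bonferroni_consistency: float
    p_bonferroni_agreement: float
    n: int
    k: int

    def to_dict(self) -> dict:
        return {
            "movement_type": self.movement_type,
            "consistency": self.consistency,
            "absolute_agreement": self.absolute_agreement,
            "F_consistency": self.consistency_test.F,
            "df_consistency": [self.consistency_test.df1, self.consistency_test.df2],
            "p_consistency": self.consistency_test.p,
            "F_agreement": self.agreement_test.F,
            "df_agreement": [self.agreement_test.df1, self.agreement_test.df2],
            "p_agreement": self.agreement_test.p,
            "p_bonferroni_consistency": self.p_bonferroni_consistency,
            "p_bonferroni_agreement": self.p_bonferroni_agreement,
            "n": self.n,
            "k": self.k,
        }


@dataclass
class FeatureTable:
    """Per-cycle classifier input: concatenated axis bin-vectors."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    source: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if not (len(self.X) == len(self.y) == len(self.groups)):
            raise ValueError("X, y and groups must be aligned")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class ClassificationResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sem: float
    confusion: np.ndarray  # row-normalized percentages
    classes: list[str]
    chosen_C: list[float]
    null_distribution: np.ndarray | None = None
    p_perm: float | None = None

    def to_dict(self) -> dict:
        out = {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "sem": float(self.sem),
            "confusion_percent": self.confusion.tolist(),
            "classes": list(self.classes),
            "chosen_C": [float(c) for c in self.chosen_C],
        }
        if self.null_distribution is not None:
            out["null_distribution"] = [float(a) for a in self.null_distribution]
        if self.p_perm is not None:
            out["p_perm"] = float(self.p_perm)
        return out


def with_seed(cfg: SimulationConfig, seed: int | None) -> SimulationConfig:
    """Return a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
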