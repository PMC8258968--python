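"""Typed pipeline configuration with YAML loading and strict key checking."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from ..datatypes import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class SimulationBlock:
    n_participants: int = 20
    cycle_duration_s: float = 2.0
    n_cycles: int = 10
    sampling_rate: float = 200.0
    accel_noise_sd: float = 0.05
    position_noise_sd: float = 0.0005
    cycle_jitter: float = 0.05
    gravity: float = 9.81
    tail_samples: int = 10


@dataclass(frozen=True)
class FilterBlock:
    cutoff_hz: float = 6.0
    order: int = 2


@dataclass(frozen=True)
class GravityBlock:
    enabled: bool = True
    value: float = 9.81


@dataclass(frozen=True)
class SyncBlock:
    max_lag_s: float = 2.0


@dataclass(frozen=True)
class SegmentBlock:
    n_bins: int = 10


@dataclass(frozen=True)
class AgreementBlock:
    bonferroni_m: int = 8


@dataclass(frozen=True)
class ClassificationBlock:
    n_folds: int = 10
    C_grid: tuple[float, ...] = tuple(10.0**k for k in range(-3, 4))
    n_perm: int = 100
    permutation_scope: str = "global"
    retune_permutations: bool = True


_BLOCKS = {
    "simulation": SimulationBlock,
    "filter": FilterBlock,
    "gravity": GravityBlock,
    "sync": SyncBlock,
    "segment": SegmentBlock,
    "agreement": AgreementBlock,
    "classification": ClassificationBlock,
}


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationBlock = field(default_factory=SimulationBlock)
    filter: FilterBlock = field(default_factory=FilterBlock)
    gravity: GravityBlock = field(default_factory=GravityBlock)
    sync: SyncBlock = field(default_factory=SyncBlock)
    segment: SegmentBlock = field(default_factory=SegmentBlock)
    agreement: AgreementBlock = field(default_factory=AgreementBlock)
    classification: ClassificationBlock = field(default_factory=ClassificationBlock)
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a nested mapping, rejecting unknown keys."""
        raw = dict(raw or {})
        kwargs = {}
        for name, block_cls in _BLOCKS.items():
            block_raw = raw.pop(name, {}) or {}
            known = {f.name for f in fields(block_cls)}
            unknown = set(block_raw) - known
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            if "C_grid" in block_raw:
                block_raw = {**block_raw, "C_grid": tuple(block_raw["C_grid"])}
            kwargs[name] = block_cls(**block_raw)
        for scalar in ("seed", "output_dir"):
            if scalar in raw:
                kwargs[scalar] = raw.pop(scalar)
        if raw:
            raise ValueError(f"unknown top-level config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path), encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classification"]["C_grid"] = list(d["classification"]["C_grid"])
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        """The simulator view of this configuration."""
        s = self.simulation
        return SimulationConfig(
            sampling_rate=s.sampling_rate,
            accel_noise_sd=s.accel_noise_sd,
            position_noise_sd=s.position_noise_sd,
            cycle_jitter=s.cycle_jitter,
            gravity=s.gravity,
            tail_samples=s.tail_samples,
            seed=self.seed if seed is None else seed,
        )

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (defaults when ``path`` is None), apply overrides."""
    cfg = PipelineConfig.from_yaml(path) if path else PipelineConfig()
    if overrides:
        merged = cfg.to_dict()
        for key, value in overrides.items():
            blk, _, leaf = key.partition(".")
            if leaf:
                merged.setdefault(blk, {})[leaf] = value
            else:
                merged[blk] = value
        cfg = PipelineConfig.from_dict(merged)
    return cfg
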