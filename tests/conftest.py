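"""Shared fixtures: simulated designs at several scales.

The full 20-participant design is expensive (~15 s to simulate and
preprocess), so it is built once per session and shared by the
acceptance tests; smaller designs serve the unit/property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from kidmotion.pipeline_io.config import PipelineConfig
from kidmotion.pipeline_io.runner import PairedRecording, dataset_to_cycles
from kidmotion.synthetic import default_movement_specs, generate_dataset


def _pairs_from_dataset(dataset):
    return [
        PairedRecording(
            participant_id=r.participant_id,
            movement_type=r.movement_type.value,
            imu=r.imu,
            mocap=r.mocap,
        )
        for r in dataset
    ]


def make_cycles(n_participants: int, seed: int, **overrides):
    """Simulate a design and run it through preprocessing into cycle sets."""
    sim = {"n_participants": n_participants, **overrides}
    cfg = PipelineConfig.from_dict({"simulation": sim, "seed": seed})
    dataset = generate_dataset(
        n_participants,
        default_movement_specs(
            cycle_duration=sim.get("cycle_duration_s", 2.0),
            n_cycles=sim.get("n_cycles", 10),
        ),
        cfg.simulation_config(),
    )
    cycles_kid, cycles_mocap, lags = dataset_to_cycles(_pairs_from_dataset(dataset), cfg)
    return dataset, cycles_kid, cycles_mocap, lags


@pytest.fixture(scope="session")
def full_design():
    """The complete study design: 20 participants x 4 types x 10 cycles."""
    dataset, cycles_kid, cycles_mocap, lags = make_cycles(20, seed=1)
    return {
        "dataset": dataset,
        "cycles_kid": cycles_kid,
        "cycles_mocap": cycles_mocap,
        "lags": lags,
    }


@pytest.fixture(scope="session")
def small_design():
    """4 participants, same structure: cheap stand-in for CV properties."""
    dataset, cycles_kid, cycles_mocap, lags = make_cycles(4, seed=7)
    return {
        "dataset": dataset,
        "cycles_kid": cycles_kid,
        "cycles_mocap": cycles_mocap,
        "lags": lags,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
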