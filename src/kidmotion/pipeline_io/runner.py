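"""End-to-end validation pipeline: simulate/ingest through final report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..agreement import agreement_analysis
from ..classification import (
    build_features,
    cross_classify,
    nested_cv_svm,
    permutation_test,
    permutation_test_cross,
)
from ..datatypes import CycleSet, ImuRecording, MarkerTrajectory, MovementSpec
from ..preprocess import preprocess_imu, preprocess_mocap
from ..sync_segment import align_and_trim, build_cycle_set, estimate_lag
from ..synthetic import SyntheticDataset, generate_dataset
from .config import PipelineConfig
from .formats import read_imu_csv, read_mocap_csv, write_imu_csv, write_mocap_csv

__all__ = [
    "RunReport",
    "run_validation_pipeline",
    "dataset_to_cycles",
    "write_dataset_dir",
    "load_dataset_dir",
    "simulate_to_dir",
    "PairedRecording",
]

log = logging.getLogger("kidmotion")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PairedRecording:
    """One participant x movement-type pair of raw streams."""

    participant_id: str
    movement_type: str
    imu: ImuRecording
    mocap: MarkerTrajectory


@dataclass
class RunReport:
    """Serializable summary of one full pipeline run."""

    icc: dict
    classification: dict
    lags: list[dict]
    provenance: dict
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "icc": self.icc,
            "classification": self.classification,
            "lags": self.lags,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunReport":
        with open(Path(path), encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            icc=d["icc"],
            classification=d["classification"],
            lags=d["lags"],
            provenance=d["provenance"],
            schema_version=d["schema_version"],
        )


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def dataset_to_cycles(
    pairs: list[PairedRecording], cfg: PipelineConfig
) -> tuple[CycleSet, CycleSet, list[dict]]:
    """Preprocess, synchronize, segment and bin every paired recording."""
    kid_parts, mocap_parts, lag_rows = [], [], []
    max_lag = int(round(cfg.sync.max_lag_s * cfg.simulation.sampling_rate))
    gravity = cfg.gravity.value if cfg.gravity.enabled else 0.0
    for pair in pairs:
        kid = preprocess_imu(
            pair.imu, cutoff=cfg.filter.cutoff_hz, order=cfg.filter.order, gravity=gravity
        )
        mocap = preprocess_mocap(pair.mocap, cutoff=cfg.filter.cutoff_hz, order=cfg.filter.order)
        lag = estimate_lag(mocap.am, kid.am, max_lag=min(max_lag, len(kid) - 2))
        kid_al, mocap_al = align_and_trim(kid, mocap, lag)
        # markers travel with the IMU stream; a residual sync error of a
        # few samples may push the outermost markers just past the edges,
        # so clip rather than drop (a cycle must not vanish)
        boundaries = np.unique(np.clip(pair.imu.markers - lag, 0, len(kid_al)))
        if boundaries.size != pair.imu.markers.size:
            raise ValueError(
                f"{pair.participant_id}/{pair.movement_type}: "
                "cycle markers collapsed during alignment (sync failure?)"
            )
        if boundaries.size < 2:
            raise ValueError(
                f"{pair.participant_id}/{pair.movement_type}: "
                "not enough cycle markers survive alignment"
            )
        kid_parts.append(
            build_cycle_set(kid_al, boundaries, pair.participant_id, pair.movement_type, cfg.segment.n_bins)
        )
        mocap_parts.append(
            build_cycle_set(mocap_al, boundaries, pair.participant_id, pair.movement_type, cfg.segment.n_bins)
        )
        lag_rows.append(
            {
                "participant_id": pair.participant_id,
                "movement_type": str(pair.movement_type),
                "lag_samples": int(lag),
            }
        )
    return CycleSet.concatenate(kid_parts), CycleSet.concatenate(mocap_parts), lag_rows


def _simulated_pairs(cfg: PipelineConfig) -> list[PairedRecording]:
    specs = [
        MovementSpec(mt, cycle_duration=cfg.simulation.cycle_duration_s, n_cycles=cfg.simulation.n_cycles)
        for mt in ("horizontal", "vertical", "elliptical", "figure_eight")
    ]
    dataset = generate_dataset(cfg.simulation.n_participants, specs, cfg.simulation_config())
    return [
        PairedRecording(
            participant_id=rec.participant_id,
            movement_type=rec.movement_type.value,
            imu=rec.imu,
            mocap=rec.mocap,
        )
        for rec in dataset
    ]


def run_validation_pipeline(
    cfg: PipelineConfig,
    pairs: list[PairedRecording] | None = None,
    n_perm: int | None = None,
) -> RunReport:
    """Execute the full pipeline and assemble a reproducible report.

    With ``pairs=None`` the study design is simulated from the config
    seed; otherwise the given raw recordings are ingested.  ``n_perm``
    overrides the configured permutation count (0 skips permutation
    testing entirely).
    """
    log.info(
        "design decisions in effect: filter=%s Hz order %s (zero-phase), gravity=%s (%s), "
        "max_lag=%s s, n_bins=%s, bonferroni_m=%s, C_grid=%s",
        cfg.filter.cutoff_hz,
        cfg.filter.order,
        cfg.gravity.enabled,
        cfg.gravity.value,
        cfg.sync.max_lag_s,
        cfg.segment.n_bins,
        cfg.agreement.bonferroni_m,
        list(cfg.classification.C_grid),
    )
    if n_perm is None:
        n_perm = cfg.classification.n_perm
    with _stage("simulate/ingest"):
        if pairs is None:
            pairs = _simulated_pairs(cfg)
    with _stage("preprocess+sync+segment"):
        cycles_kid, cycles_mocap, lag_rows = dataset_to_cycles(pairs, cfg)
    with _stage("agreement"):
        icc = agreement_analysis(cycles_kid, cycles_mocap, m=cfg.agreement.bonferroni_m)
    with _stage("classification"):
        feats_kid = build_features(cycles_kid)
        feats_mocap = build_features(cycles_mocap)
        cls_cfg = cfg.classification
        common = dict(n_folds=cls_cfg.n_folds, C_grid=cls_cfg.C_grid, seed=cfg.seed)
        res_kid = nested_cv_svm(feats_kid, **common)
        res_mocap = nested_cv_svm(feats_mocap, **common)
        res_m2k = cross_classify(feats_mocap, feats_kid, **common)
        res_k2m = cross_classify(feats_kid, feats_mocap, **common)
    if n_perm > 0:
        with _stage("permutation tests"):
            for feats, res in ((feats_kid, res_kid), (feats_mocap, res_mocap)):
                null, p = permutation_test(
                    feats,
                    res.mean_accuracy,
                    n_perm=n_perm,
                    seed=cfg.seed,
                    n_folds=cls_cfg.n_folds,
                    C_grid=cls_cfg.C_grid,
                    retune=cls_cfg.retune_permutations,
                    scope=cls_cfg.permutation_scope,
                )
                res.null_distribution, res.p_perm = null, p
            for train, test, res in (
                (feats_mocap, feats_kid, res_m2k),
                (feats_kid, feats_mocap, res_k2m),
            ):
                null, p = permutation_test_cross(
                    train,
                    test,
                    res.mean_accuracy,
                    n_perm=n_perm,
                    seed=cfg.seed,
                    n_folds=cls_cfg.n_folds,
                    C_grid=cls_cfg.C_grid,
                    retune=cls_cfg.retune_permutations,
                )
                res.null_distribution, res.p_perm = null, p
    provenance = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "software_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "n_recording_pairs": len(pairs),
        "n_cycles": int(cycles_kid.n_cycles),
    }
    return RunReport(
        icc={mt: r.to_dict() for mt, r in icc.items()},
        classification={
            "kid": res_kid.to_dict(),
            "mocap": res_mocap.to_dict(),
            "cross_mocap_to_kid": res_m2k.to_dict(),
            "cross_kid_to_mocap": res_k2m.to_dict(),
        },
        lags=lag_rows,
        provenance=provenance,
    )


def write_dataset_dir(pairs: list[PairedRecording], out_dir) -> Path:
    """Write raw CSV pairs plus a manifest into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair in pairs:
        stem = f"{pair.participant_id}_{pair.movement_type}"
        imu_path = out_dir / f"{stem}_imu.csv"
        mocap_path = out_dir / f"{stem}_mocap.csv"
        write_imu_csv(pair.imu, imu_path)
        write_mocap_csv(pair.mocap, mocap_path)
        rows.append(
            {
                "participant_id": pair.participant_id,
                "movement_type": str(pair.movement_type),
                "imu_file": imu_path.name,
                "mocap_file": mocap_path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset_dir(data_dir) -> list[PairedRecording]:
    """Load raw CSV pairs listed in ``manifest.csv`` under ``data_dir``."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise ValueError(f"no manifest.csv in {data_dir}")
    rows = pd.read_csv(manifest)
    pairs = []
    for _, row in rows.iterrows():
        pairs.append(
            PairedRecording(
                participant_id=str(row["participant_id"]),
                movement_type=str(row["movement_type"]),
                imu=read_imu_csv(
                    data_dir / row["imu_file"],
                    participant_id=str(row["participant_id"]),
                    movement_type=row["movement_type"],
                ),
                mocap=read_mocap_csv(data_dir / row["mocap_file"]),
            )
        )
    return pairs


def simulate_to_dir(cfg: PipelineConfig, out_dir) -> Path:
    """Simulate the configured design and persist it as raw CSVs."""
    pairs = _simulated_pairs(cfg)
    return write_dataset_dir(pairs, out_dir)
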