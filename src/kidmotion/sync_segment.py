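"""Stream synchronization, cycle segmentation and time normalization.

The two acceleration streams are aligned by maximizing the Pearson
correlation of their magnitude channels over non-negative integer lags
(the IMU stream is the delayed one), trimmed to a common length, cut
into cycles at the recorded event markers, and each cycle is summarized
by within-bin means over a fixed number of normalized-time bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CycleSet, WorldAccelSeries

__all__ = [
    "estimate_lag",
    "align_and_trim",
    "segment_cycles",
    "resample_bins",
    "build_cycle_set",
    "DEFAULT_N_BINS",
    "DEFAULT_MAX_LAG_S",
]

DEFAULT_N_BINS = 10
DEFAULT_MAX_LAG_S = 2.0


def estimate_lag(am_ref: np.ndarray, am_query: np.ndarray, max_lag: int) -> int:
    """Non-negative shift of the query stream that best matches the reference.

    The reference (optical) magnitude series is kept fixed while the query
    (IMU) series is shifted forward by 0..``max_lag`` samples; the lag with
    the highest Pearson correlation over the overlapping region wins, the
    smallest lag on exact ties.
    """
    am_ref = np.asarray(am_ref, dtype=float)
    am_query = np.asarray(am_query, dtype=float)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if np.std(am_ref) == 0 or np.std(am_query) == 0:
        raise ValueError("cannot correlate a constant series")
    best_lag, best_r = 0, -np.inf
    for lag in range(max_lag + 1):
        overlap = min(len(am_ref), len(am_query) - lag)
        if overlap < 2:
            if lag == 0:
                raise ValueError("streams do not overlap")
            break
        a = am_ref[:overlap]
        b = am_query[lag : lag + overlap]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r:
            best_lag, best_r = lag, r
    if not np.isfinite(best_r):
        raise ValueError("no valid overlap found within max_lag")
    return best_lag


def align_and_trim(
    kid: WorldAccelSeries, mocap: WorldAccelSeries, lag: int
) -> tuple[WorldAccelSeries, WorldAccelSeries]:
    """Drop the first ``lag`` IMU samples and truncate both to a common length.

    All four channels are cut with the same lag obtained from the
    magnitude channel.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag >= len(kid):
        raise ValueError("lag exceeds IMU stream length")
    kid_cut = kid.sliced(lag, len(kid))
    n = min(len(kid_cut), len(mocap))
    if n == 0:
        raise ValueError("alignment leaves no overlapping samples")
    return kid_cut.sliced(0, n), mocap.sliced(0, n)


def segment_cycles(series: WorldAccelSeries, boundaries) -> list[np.ndarray]:
    """Cut the stacked channels into half-open per-cycle blocks.

    ``boundaries`` are sample indices; cycle ``k`` spans
    ``[boundaries[k], boundaries[k+1])``, so ``len(boundaries) - 1``
    cycles are returned, each an ``(len, 4)`` array in channel order
    (ax, ay, az, am).
    """
    boundaries = np.asarray(boundaries, dtype=np.intp)
    if boundaries.size < 2:
        raise ValueError("need at least 2 boundaries")
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    if boundaries[0] < 0 or boundaries[-1] > len(series):
        raise ValueError("boundaries out of range")
    stacked = series.stacked()
    return [stacked[boundaries[k] : boundaries[k + 1]] for k in range(boundaries.size - 1)]


def resample_bins(segment: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Summarize one cycle on a normalized (%) timescale by within-bin means.

    The cycle is partitioned into ``n_bins`` contiguous, near-equal sample
    blocks (any remainder goes to the earliest bins) and each bin takes
    the mean of its block, per channel.
    """
    segment = np.asarray(segment, dtype=float)
    squeeze = segment.ndim == 1
    if squeeze:
        segment = segment[:, None]
    length = segment.shape[0]
    if length < n_bins:
        raise ValueError(f"cycle of {length} samples shorter than {n_bins} bins")
    base, rem = divmod(length, n_bins)
    sizes = np.full(n_bins, base, dtype=np.intp)
    sizes[:rem] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    binned = np.stack(
        [segment[edges[i] : edges[i + 1]].mean(axis=0) for i in range(n_bins)]
    )
    return binned[:, 0] if squeeze else binned


def build_cycle_set(
    series: WorldAccelSeries,
    boundaries,
    participant_id: str,
    movement_type: str,
    n_bins: int = DEFAULT_N_BINS,
) -> CycleSet:
    """Segment one recording and time-normalize every cycle."""
    segments = segment_cycles(series, boundaries)
    data = np.stack([resample_bins(seg, n_bins) for seg in segments])
    labels = pd.DataFrame(
        {
            "participant_id": participant_id,
            "movement_type": str(movement_type),
            "cycle_index": np.arange(len(segments)),
            "source": series.source,
        }
    )
    return CycleSet(data=data, labels=labels)
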