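"""Inter-device agreement via intraclass correlation coefficients.

For each movement type, the magnitude channel is averaged per time-bin
across each participant's cycles, giving an ``n x 2`` table whose rows
are participant x bin combinations and whose columns are the two devices.
Two ICC indices are computed from its two-way crossed ANOVA:

* consistency        ``(MSR - MSE) / MSR`` — offset-insensitive;
* absolute agreement ``(MSR - MSE) / (MSR + (MSC - MSE) / n)`` —
  penalizes systematic between-device offsets.

Both are tested against the null of zero ICC with F statistics, and the
p-values are Bonferroni-adjusted over the family of reported tests.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import f as f_dist

from .datatypes import CycleSet, IccResult, IccTest, MeanSquares

__all__ = [
    "build_agreement_table",
    "two_way_mean_squares",
    "icc_consistency",
    "icc_absolute_agreement",
    "icc_significance",
    "bonferroni",
    "agreement_analysis",
    "DEFAULT_BONFERRONI_M",
]

#: 4 movement types x 2 ICC indices
DEFAULT_BONFERRONI_M = 8


def _participant_bin_means(cycles: CycleSet, movement_type: str) -> dict[str, np.ndarray]:
    mask = cycles.labels["movement_type"].to_numpy() == str(movement_type)
    if not mask.any():
        raise ValueError(f"no cycles for movement type {movement_type!r}")
    am = cycles.channel("am")[mask]
    pids = cycles.labels.loc[mask, "participant_id"].to_numpy()
    return {pid: am[pids == pid].mean(axis=0) for pid in sorted(set(pids))}


def build_agreement_table(
    cycles_kid: CycleSet, cycles_mocap: CycleSet, movement_type: str
) -> np.ndarray:
    """Per-participant, per-bin magnitude means for both devices.

    Returns an ``(participants * bins) x 2`` array with columns
    (IMU, optical); the magnitude of each participant is first averaged
    across that participant's cycles, separately for the requested
    movement type.
    """
    kid = _participant_bin_means(cycles_kid, movement_type)
    mocap = _participant_bin_means(cycles_mocap, movement_type)
    if set(kid) != set(mocap):
        raise ValueError("participant sets differ between devices")
    if cycles_kid.n_bins != cycles_mocap.n_bins:
        raise ValueError("bin counts differ between devices")
    rows = [
        (kid[pid][b], mocap[pid][b])
        for pid in sorted(kid)
        for b in range(cycles_kid.n_bins)
    ]
    return np.asarray(rows, dtype=float)


def two_way_mean_squares(table: np.ndarray) -> MeanSquares:
    """Two-way crossed ANOVA decomposition of an ``n x k`` table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    n, k = table.shape
    if n < 2 or k < 2:
        raise ValueError("need at least a 2 x 2 table")
    if not np.isfinite(table).all():
        raise ValueError("table contains missing or non-finite cells")
    grand = table.mean()
    ssr = k * float(((table.mean(axis=1) - grand) ** 2).sum())
    ssc = n * float(((table.mean(axis=0) - grand) ** 2).sum())
    sst = float(((table - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    return MeanSquares(
        msr=ssr / (n - 1),
        msc=ssc / (k - 1),
        mse=sse / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_consistency(ms: MeanSquares) -> float:
    """Offset-insensitive ICC: ``(MSR - MSE) / MSR``."""
    if ms.msr <= 0:
        raise ValueError("consistency undefined for MSR = 0")
    value = (ms.msr - ms.mse) / ms.msr
    if value < 0:
        warnings.warn(f"negative consistency ICC ({value:.4f}) reported as computed", stacklevel=2)
    return value


def icc_absolute_agreement(ms: MeanSquares) -> float:
    """Offset-sensitive ICC: ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``."""
    denom = ms.msr + (ms.msc - ms.mse) / ms.n
    if denom <= 0:
        raise ValueError("absolute agreement undefined for non-positive denominator")
    value = (ms.msr - ms.mse) / denom
    if value < 0:
        warnings.warn(f"negative agreement ICC ({value:.4f}) reported as computed", stacklevel=2)
    return value


def icc_significance(ms: MeanSquares, which: str = "consistency") -> IccTest:
    """F-test of an ICC against the null hypothesis ICC = 0.

    For consistency, ``F = MSR / MSE`` with ``(n-1, (n-1)(k-1))`` degrees
    of freedom.  For absolute agreement the average-measures test of
    McGraw & Wong (1996) is used; under a zero-ICC null its linear
    combination of mean squares collapses to ``MSE`` and the Satterthwaite
    denominator degrees of freedom reduce to ``(n-1)(k-1)`` as well, so
    both indices share the same null distribution.
    """
    if which not in ("consistency", "agreement"):
        raise ValueError("which must be 'consistency' or 'agreement'")
    df1 = float(ms.df_rows)
    if ms.mse == 0:
        return IccTest(F=np.inf, df1=df1, df2=float(ms.df_error), p=0.0, degenerate=True)
    # null value rho0 = 0: the agreement-test denominator a*MSC + b*MSE
    # has a = 0, b = 1, hence identical F and df for both indices
    a, b = 0.0, 1.0
    denom = a * ms.msc + b * ms.mse
    df2 = denom**2 / (
        (a * ms.msc) ** 2 / ms.df_cols + (b * ms.mse) ** 2 / ms.df_error
    )
    F = ms.msr / denom
    p = float(f_dist.sf(F, df1, df2))
    return IccTest(F=float(F), df1=df1, df2=float(df2), p=p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` per value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def agreement_analysis(
    cycles_kid: CycleSet,
    cycles_mocap: CycleSet,
    m: int = DEFAULT_BONFERRONI_M,
) -> dict[str, IccResult]:
    """Both ICC indices with significance, one result per movement type."""
    types = list(dict.fromkeys(cycles_kid.labels["movement_type"]))
    results: dict[str, IccResult] = {}
    for mt in types:
        table = build_agreement_table(cycles_kid, cycles_mocap, mt)
        ms = two_way_mean_squares(table)
        cons_test = icc_significance(ms, "consistency")
        agr_test = icc_significance(ms, "agreement")
        results[mt] = IccResult(
            movement_type=mt,
            consistency=icc_consistency(ms),
            absolute_agreement=icc_absolute_agreement(ms),
            consistency_test=cons_test,
            agreement_test=agr_test,
            p_bonferroni_consistency=float(bonferroni([cons_test.p], m)[0]),
            p_bonferroni_agreement=float(bonferroni([agr_test.p], m)[0]),
            n=ms.n,
            k=ms.k,
        )
    return results
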