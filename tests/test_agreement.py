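"""ICC agreement tests, including independent ANOVA oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kidmotion.agreement import (
    agreement_analysis,
    bonferroni,
    build_agreement_table,
    icc_absolute_agreement,
    icc_consistency,
    icc_significance,
    two_way_mean_squares,
)
from kidmotion.datatypes import MeanSquares

WORKED_TABLE = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])


def brute_force_anova(table: np.ndarray) -> tuple[float, float, float]:
    """Loop-based two-way crossed ANOVA, deliberately naive."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(table[i]) / k for i in range(n)]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((rm - grand) ** 2 for rm in row_means)
    ssc = n * sum((cm - grand) ** 2 for cm in col_means)
    sse = sum(
        (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


class TestTwoWayMeanSquares:
    def test_worked_table(self):
        ms = two_way_mean_squares(WORKED_TABLE)
        assert ms.msr == pytest.approx(40.0 / 3.0)
        assert ms.msc == pytest.approx(2.0)
        assert ms.mse == pytest.approx(0.0, abs=1e-12)

    def test_all_cells_equal(self):
        ms = two_way_mean_squares(np.full((5, 2), 3.0))
        assert ms.msr == ms.msc == ms.mse == 0.0

    def test_decomposition_identity(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(2, 12)), int(rng.integers(2, 5))
            table = rng.normal(size=(n, k))
            ms = two_way_mean_squares(table)
            sst = float(((table - table.mean()) ** 2).sum())
            recomposed = ms.msr * (n - 1) + ms.msc * (k - 1) + ms.mse * (n - 1) * (k - 1)
            assert recomposed == pytest.approx(sst, abs=1e-9)

    def test_missing_cells_rejected(self):
        bad = WORKED_TABLE.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            two_way_mean_squares(bad)

    @pytest.mark.filterwarnings("ignore::UserWarning")  # negative-ICC notices
    def test_oracle_equivalence_50_random_tables(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(2, 15)), int(rng.integers(2, 4))
            table = rng.normal(scale=rng.uniform(0.5, 5), size=(n, k))
            ms = two_way_mean_squares(table)
            msr, msc, mse = brute_force_anova(table)
            assert ms.msr == pytest.approx(msr, abs=1e-10)
            assert ms.msc == pytest.approx(msc, abs=1e-10)
            assert ms.mse == pytest.approx(mse, abs=1e-10)
            # the ICC formulas applied to oracle mean squares agree too
            oracle_ms = MeanSquares(msr=msr, msc=msc, mse=mse, n=n, k=k)
            if ms.msr > 0:
                assert icc_consistency(ms) == pytest.approx(
                    icc_consistency(oracle_ms), abs=1e-10
                )
            if ms.msr + (ms.msc - ms.mse) / n > 0:
                assert icc_absolute_agreement(ms) == pytest.approx(
                    icc_absolute_agreement(oracle_ms), abs=1e-10
                )


class TestIccFormulas:
    def test_worked_table_consistency(self):
        assert icc_consistency(two_way_mean_squares(WORKED_TABLE)) == pytest.approx(1.0)

    def test_worked_table_absolute_agreement(self):
        value = icc_absolute_agreement(two_way_mean_squares(WORKED_TABLE))
        assert value == pytest.approx((40 / 3) / (40 / 3 + 2 / 4), abs=1e-9)
        assert value == pytest.approx(0.9639, abs=1e-4)

    def test_consistency_zero_when_msr_equals_mse(self):
        ms = MeanSquares(msr=10.0, msc=1.0, mse=10.0, n=10, k=2)
        assert icc_consistency(ms) == 0.0

    def test_identical_columns_perfect(self, rng):
        col = rng.normal(size=20)
        ms = two_way_mean_squares(np.column_stack([col, col]))
        assert icc_consistency(ms) == pytest.approx(1.0)
        assert icc_absolute_agreement(ms) == pytest.approx(1.0)

    def test_agreement_reduces_to_consistency_when_msc_equals_mse(self):
        ms = MeanSquares(msr=8.0, msc=2.0, mse=2.0, n=4, k=2)
        # (MSR - MSE)/(MSR + (MSC-MSE)/n) == (MSR - MSE)/MSR when MSC == MSE
        assert icc_absolute_agreement(ms) == pytest.approx(icc_consistency(ms), abs=1e-12)

    def test_msr_zero_errors(self):
        ms = MeanSquares(msr=0.0, msc=1.0, mse=0.0, n=4, k=2)
        with pytest.raises(ValueError):
            icc_consistency(ms)

    def test_negative_icc_warned_not_clipped(self):
        ms = MeanSquares(msr=1.0, msc=0.5, mse=2.0, n=10, k=2)
        with pytest.warns(UserWarning, match="negative"):
            assert icc_consistency(ms) == pytest.approx(-1.0)

    def test_offset_sensitivity_contract(self, rng):
        base = rng.normal(size=30)
        table = np.column_stack([base, base + rng.normal(0, 0.1, 30)])
        shifted = table.copy()
        shifted[:, 1] += 5.0
        ms0, ms1 = two_way_mean_squares(table), two_way_mean_squares(shifted)
        assert icc_consistency(ms1) == pytest.approx(icc_consistency(ms0), abs=1e-10)
        assert icc_absolute_agreement(ms1) < icc_absolute_agreement(ms0)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        table = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        n, k = table.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": table.ravel(),
            }
        )
        icc = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        ms = two_way_mean_squares(table)
        icc_ck = icc.loc[icc["Type"] == "ICC(C,k)"].iloc[0]
        icc_ak = icc.loc[icc["Type"] == "ICC(A,k)"].iloc[0]
        assert icc_consistency(ms) == pytest.approx(float(icc_ck["ICC"]), abs=1e-9)
        assert icc_absolute_agreement(ms) == pytest.approx(float(icc_ak["ICC"]), abs=1e-9)
        t = icc_significance(ms, "consistency")
        assert t.F == pytest.approx(float(icc_ck["F"]), abs=1e-9)
        assert t.p == pytest.approx(float(icc_ck["pval"]), abs=1e-9)


class TestSignificance:
    def test_null_behavior_f_equals_one(self):
        ms = MeanSquares(msr=4.0, msc=1.0, mse=4.0, n=50, k=2)
        t = icc_significance(ms, "consistency")
        assert t.F == pytest.approx(1.0)
        assert t.p > 0.05

    def test_degenerate_mse_zero(self):
        ms = two_way_mean_squares(WORKED_TABLE)
        t = icc_significance(ms, "consistency")
        assert t.degenerate
        assert np.isinf(t.F)
        assert t.p == 0.0

    def test_agreement_test_shares_null_distribution(self):
        ms = MeanSquares(msr=9.0, msc=2.0, mse=3.0, n=40, k=2)
        c = icc_significance(ms, "consistency")
        a = icc_significance(ms, "agreement")
        assert c.F == pytest.approx(a.F)
        assert c.df2 == pytest.approx(a.df2)

    def test_invalid_which(self):
        ms = MeanSquares(msr=1.0, msc=1.0, mse=1.0, n=4, k=2)
        with pytest.raises(ValueError):
            icc_significance(ms, "both")

    @pytest.mark.slow
    def test_type_one_error_calibration(self):
        """Under a true null the 5% test rejects ~5% of the time."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            table = rng.normal(size=(200, 2))
            t = icc_significance(two_way_mean_squares(table), "consistency")
            rejections += t.p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestBonferroni:
    def test_worked_values(self):
        assert bonferroni([0.01], 8)[0] == pytest.approx(0.08)
        assert bonferroni([0.4], 8)[0] == 1.0
        assert bonferroni([0.3], 1)[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)

    @given(st.floats(0, 1), st.integers(1, 50))
    @settings(max_examples=50, deadline=None)
    def test_capped_and_monotone(self, p, m):
        out = float(bonferroni([p], m)[0])
        assert 0 <= out <= 1
        assert out >= p or out == 1.0


class TestAgreementTable:
    def test_shape_small_design(self, small_design):
        table = build_agreement_table(
            small_design["cycles_kid"], small_design["cycles_mocap"], "horizontal"
        )
        assert table.shape == (4 * 10, 2)  # participants x bins

    def test_single_participant_identical_cycles(self):
        import pandas as pd

        from kidmotion.datatypes import CycleSet

        bins = np.arange(10.0)
        data = np.tile(bins[None, :, None], (3, 1, 4))  # 3 identical cycles
        labels = pd.DataFrame(
            {
                "participant_id": "p01",
                "movement_type": "vertical",
                "cycle_index": range(3),
                "source": "kid",
            }
        )
        cs_kid = CycleSet(data=data, labels=labels)
        cs_mocap = CycleSet(data=data.copy(), labels=labels.assign(source="mocap"))
        table = build_agreement_table(cs_kid, cs_mocap, "vertical")
        np.testing.assert_allclose(table[:, 0], bins)
        np.testing.assert_allclose(table[:, 1], bins)

    def test_unmatched_participants_rejected(self, small_design):
        kid = small_design["cycles_kid"]
        mocap = small_design["cycles_mocap"]
        mask = mocap.labels["participant_id"] != "p01"
        from kidmotion.datatypes import CycleSet

        reduced = CycleSet(
            data=mocap.data[mask.to_numpy()], labels=mocap.labels[mask].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="participant sets"):
            build_agreement_table(kid, reduced, "horizontal")

    def test_zero_noise_columns_nearly_equal(self):
        from tests.conftest import make_cycles

        _, kid, mocap, _ = make_cycles(
            2, seed=3, accel_noise_sd=0.0, position_noise_sd=0.0
        )
        for mt in ("horizontal", "elliptical"):
            table = build_agreement_table(kid, mocap, mt)
            assert np.abs(table[:, 0] - table[:, 1]).max() < 0.05


def test_agreement_analysis_end_to_end(small_design):
    results = agreement_analysis(small_design["cycles_kid"], small_design["cycles_mocap"])
    assert set(results) == {"horizontal", "vertical", "elliptical", "figure_eight"}
    for res in results.values():
        assert res.consistency > 0.95
        assert res.absolute_agreement <= res.consistency + 1e-12
        assert res.p_bonferroni_consistency == pytest.approx(
            min(1.0, 8 * res.consistency_test.p)
        )
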