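import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from istpdose import (
    comparison_records,
    cycle_dependency_table,
    mann_whitney,
    rad,
    timepoint_dependency_table,
    wilcoxon_signed_rank,
)
from istpdose.evaluation import UndefinedReferenceError, cycle_group


class TestRad:
    @pytest.mark.parametrize(
        "stp, mtp, expected",
        [(1.0, 1.0, 0.0), (1.27, 1.0, 27.0), (0.8, 1.0, 20.0)],
    )
    def test_values(self, stp, mtp, expected):
        assert rad(stp, mtp) == pytest.approx(expected)

    def test_signed_variant_keeps_direction(self):
        assert rad(0.8, 1.0, signed=True) == pytest.approx(-20.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UndefinedReferenceError):
            rad(1.0, 0.0)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            a, b, c = rng.uniform(0.1, 10, 3)
            assert rad(c * a, c * b) == pytest.approx(rad(a, b), rel=1e-12)


def records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "cycle", "organ", "t_sc_hours", "method", "tia_MBq_h"],
    )


class TestComparisonRecords:
    def test_join_and_rad(self):
        stp = records_frame([("P1", 1, "liver", 20.0, "istp", 127.0)])
        mtp = pd.DataFrame(
            [("P1", 1, "liver", 100.0)],
            columns=["patient_id", "cycle", "organ", "tia_MBq_h"],
        )
        rec = comparison_records(stp, mtp)
        assert rec["rad_percent"].iloc[0] == pytest.approx(27.0)
        assert rec["rad_signed_percent"].iloc[0] == pytest.approx(27.0)

    def test_unmatched_and_zero_reference_dropped(self):
        stp = records_frame(
            [
                ("P1", 1, "liver", 20.0, "istp", 120.0),
                ("P9", 1, "liver", 20.0, "istp", 120.0),  # no reference
                ("P2", 1, "liver", 20.0, "istp", 120.0),  # zero reference
            ]
        )
        mtp = pd.DataFrame(
            [("P1", 1, "liver", 100.0), ("P2", 1, "liver", 0.0)],
            columns=["patient_id", "cycle", "organ", "tia_MBq_h"],
        )
        rec = comparison_records(stp, mtp)
        assert list(rec["patient_id"]) == ["P1"]


class TestTimepointTable:
    def test_single_record_cell_has_sd_zero(self):
        stp = records_frame([("P1", 1, "liver", 43.0, "istp", 90.0)])
        mtp = pd.DataFrame(
            [("P1", 1, "liver", 100.0)],
            columns=["patient_id", "cycle", "organ", "tia_MBq_h"],
        )
        table = timepoint_dependency_table(comparison_records(stp, mtp))
        row = table.iloc[0]
        assert row["n"] == 1
        assert row["rad_sd_percent"] == 0.0

    def test_hanscheid_2h_flagged_out_of_method(self):
        stp = records_frame(
            [
                ("P1", 1, "liver", 2.0, "hanscheid", 90.0),
                ("P1", 1, "liver", 20.0, "hanscheid", 90.0),
                ("P1", 1, "liver", 2.0, "istp", 90.0),
            ]
        )
        mtp = pd.DataFrame(
            [("P1", 1, "liver", 100.0)],
            columns=["patient_id", "cycle", "organ", "tia_MBq_h"],
        )
        table = timepoint_dependency_table(comparison_records(stp, mtp))
        flags = table.set_index(["method", "t_sc_hours"])["out_of_method"]
        assert flags[("hanscheid", 2.0)]
        assert not flags[("hanscheid", 20.0)]
        assert not flags[("istp", 2.0)]


class TestCycleTable:
    def test_cycle_binning(self):
        assert [cycle_group(c) for c in (1, 2, 3, 4, 5, 9)] == [
            "1", "2", "3", ">=4", ">=4", ">=4",
        ]

    def build_records(self, tias):
        rows = [
            ("P%d" % i, cyc, "liver", 20.0, "istp", tia)
            for i, (cyc, tia) in enumerate(tias)
        ]
        stp = records_frame(rows)
        mtp = pd.DataFrame(
            [(f"P{i}", cyc, "liver", 100.0) for i, (cyc, _) in enumerate(tias)],
            columns=["patient_id", "cycle", "organ", "tia_MBq_h"],
        )
        return comparison_records(stp, mtp)

    def test_identical_predictions_give_identical_tables(self):
        rec = self.build_records([(1, 110.0), (1, 95.0), (2, 120.0), (4, 80.0)])
        summaries, tests = cycle_dependency_table(rec, rec.copy())
        s1 = summaries[summaries.scenario == "per_cycle"].drop(columns="scenario")
        s2 = summaries[summaries.scenario == "first_cycle_only"].drop(columns="scenario")
        assert s1.reset_index(drop=True).equals(s2.reset_index(drop=True))
        assert (tests["p_value"] == 1.0).all()

    def test_key_mismatch_rejected(self):
        rec = self.build_records([(1, 110.0), (2, 120.0)])
        with pytest.raises(ValueError, match="keys differ"):
            cycle_dependency_table(rec, rec.iloc[[0]])


def wilcoxon_oracle(x, y):
    """Exact two-sided p by enumerating all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    t_obs = float(np.sum(ranks[d > 0]))
    tplus = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    tplus = np.asarray(tplus, float)
    p_le = np.mean(tplus <= t_obs + 1e-12)
    p_ge = np.mean(tplus >= t_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def mannwhitney_oracle(x, y):
    """Exact two-sided p by enumerating all group labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    us = [
        float(np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2)
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(12):
            n = int(rng.integers(5, 9))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == y):
                continue
            got = wilcoxon_signed_rank(x, y).pvalue
            assert got == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        assert wilcoxon_signed_rank(x, y).pvalue == pytest.approx(
            wilcoxon_signed_rank(y, x).pvalue, abs=1e-12
        )

    def test_large_n_uses_normal_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal_approx"
        assert 0.0 <= res.pvalue <= 1.0


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue == pytest.approx(1.0)
        assert res.method == "exact"

    def test_fully_separated_toy_example(self):
        # U = 0 for x; exact two-sided p = 2/C(6,3) = 0.1
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(12):
            n1 = int(rng.integers(3, 6))
            n2 = int(rng.integers(3, 6))
            x = rng.integers(0, 8, n1).astype(float)
            y = rng.integers(0, 8, n2).astype(float)
            got = mann_whitney(x, y).pvalue
            assert got == pytest.approx(mannwhitney_oracle(x, y), abs=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        assert mann_whitney(x, y).pvalue == pytest.approx(
            mann_whitney(x + 7.5, y + 7.5).pvalue, abs=1e-12
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
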