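"""Coverage classification, co-occupancy counting and statistical tests."""

import math

import numpy as np
import pandas as pd
import pytest

from intragene_marks import (
    build_coverage_table,
    chi_square_test,
    classify_marked_genes,
    cooccupancy_counts,
    fisher_exact_test,
    group_signal_comparison,
    pearson_correlation,
)
from intragene_marks.occupancy_stats import MarkCoverageTable


def coverage_table(values: dict) -> MarkCoverageTable:
    cols = pd.MultiIndex.from_tuples(
        [(m, "WT") for m in values], names=["mark", "condition"]
    )
    idx = pd.Index([f"g{i}" for i in range(len(next(iter(values.values()))))],
                   name="gene_id")
    cov = pd.DataFrame(
        np.column_stack([values[m] for m in values]), index=idx, columns=cols
    )
    zeros = pd.DataFrame(0.0, index=idx, columns=cols)
    n = (~cov.isna()).astype(int)
    return MarkCoverageTable(cov, zeros, n, pd.DataFrame(index=idx))


class TestClassification:
    def test_threshold_inclusive_and_missing_excluded(self):
        table = coverage_table({"MIRA": [0.20, 0.199, np.nan, 0.8]})
        marked = classify_marked_genes(table, "MIRA")
        assert marked.tolist() == [True, False, pd.NA, True]

    def test_unknown_mark_errors(self):
        table = coverage_table({"MIRA": [0.5]})
        with pytest.raises(KeyError, match="H3K9me3"):
            classify_marked_genes(table, "H3K9me3")


class TestCooccupancy:
    def make(self, a, b):
        idx = pd.Index([f"g{i}" for i in range(len(a))])
        return (pd.Series(a, index=idx, dtype="boolean", name="m1"),
                pd.Series(b, index=idx, dtype="boolean", name="m2"))

    def test_enumeration_example(self):
        # genes A:{m1}, B:{m1,m2}, C:{m2}
        a, b = self.make([True, True, False], [False, True, True])
        res = cooccupancy_counts(a, b)
        assert (res.only_a, res.only_b, res.both, res.neither) == (1, 1, 1, 0)
        assert res.table.to_numpy().tolist() == [[1, 1], [1, 0]]

    def test_identical_and_disjoint(self):
        a, b = self.make([True, False], [True, False])
        res = cooccupancy_counts(a, b)
        assert res.only_a == res.only_b == 0 and res.both == 1
        a, b = self.make([True, False], [False, True])
        assert cooccupancy_counts(a, b).both == 0

    def test_counts_sum_to_universe_with_exclusions(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            raw_a = rng.choice([True, False, None], size=n)
            raw_b = rng.choice([True, False, None], size=n)
            a, b = self.make(list(raw_a), list(raw_b))
            res = cooccupancy_counts(a, b)
            expected = int((a.notna() & b.notna()).sum())
            assert res.only_a + res.only_b + res.both + res.neither == expected

    def test_mismatched_universes_error(self):
        a = pd.Series([True], index=["g1"], dtype="boolean")
        b = pd.Series([True], index=["g2"], dtype="boolean")
        with pytest.raises(ValueError, match="universe"):
            cooccupancy_counts(a, b)


def chi_square_oracle(table: np.ndarray) -> float:
    """Closed-form Pearson statistic Sum (O-E)^2 / E."""
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (table[i, j] - e) ** 2 / e
    return stat


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed p by full hypergeometric enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k: int) -> float:
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


class TestChiSquare:
    def test_derived_examples(self):
        res = chi_square_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1
        res = chi_square_test([[5, 0], [0, 5]])
        assert res.statistic == pytest.approx(10.0, rel=1e-12)

    def test_expected_table_gives_zero_statistic(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_zero_margin_advises_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi_square_test([[5, 0], [5, 0]])


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 3], [3, 3]], 1.0),
            ([[0, 5], [5, 0]], 2 / 252),
            ([[13, 0], [13, 0]], 1.0),
        ],
    )
    def test_examples(self, table, expected):
        assert fisher_exact_test(table).p_two_tailed == pytest.approx(expected, rel=1e-7)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_test([[1, 2, 3], [4, 5, 6]])

    def test_matches_enumeration_on_small_tables(self):
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        if a + b + c + d == 0:
                            continue
                        got = fisher_exact_test([[a, b], [c, d]]).p_two_tailed
                        assert got == pytest.approx(
                            fisher_oracle(a, b, c, d), rel=1e-7
                        ), (a, b, c, d)


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_correlation(x, x).r == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson_correlation([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(3 / math.sqrt(2 * 14 / 3), rel=1e-12)
        assert res.n == 3

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = pearson_correlation(x, y).r
        assert pearson_correlation(3.5 * x + 2, 0.1 * y - 7).r == pytest.approx(base)
        assert pearson_correlation(-x, y).r == pytest.approx(-base)

    def test_missing_pairs_dropped_and_series_aligned(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0], index=list("abcde"))
        y = pd.Series([5.0, 4.0, 3.0, 2.0, np.nan], index=list("abcde"))
        assert pearson_correlation(x, y).n == 3

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 3"):
            pearson_correlation([1, 2], [1, 2])


class TestGroupComparison:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=60)
        res = group_signal_comparison({"a": vals, "b": vals.copy()})
        assert res.loc[0, "p_bonferroni"] >= 0.9

    def test_three_groups_bonferroni_factor(self):
        rng = np.random.default_rng(10)
        groups = {k: rng.normal(size=20) for k in "abc"}
        res = group_signal_comparison(groups)
        assert len(res) == 3
        assert res["p_bonferroni"].tolist() == pytest.approx(
            np.minimum(1.0, res["p_raw"] * 3).tolist()
        )

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(11)
        res = group_signal_comparison(
            {"lo": rng.normal(0, 1, 50), "hi": rng.normal(5, 1, 50)}
        )
        assert res.loc[0, "p_bonferroni"] < 1e-3

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_signal_comparison({"a": [1.0], "b": [1.0, 2.0]})
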