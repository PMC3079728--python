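"""Metagene binning, composite profiles and profile clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from intragene_marks import (
    AnalysisParams,
    GeneModel,
    SignalTrack,
    assign_bin_indices,
    bin_gene_profile,
    cluster_profile_matrix,
    composite_profile,
    oriented_bin_intervals,
)
from intragene_marks.profiles import BinProfile
from scipy.cluster import hierarchy


def make_gene(strand="+", tx_start=10000, length=10000, gene_id="G1"):
    tx_end = tx_start + length
    return GeneModel(gene_id, gene_id, "chr1", strand, tx_start, tx_end,
                     ((tx_start, tx_end),))


def uniform_track(lo, hi, value=1.0, spacing=100, length=50, mark="MIRA"):
    starts = np.arange(lo, hi - length, spacing)
    return SignalTrack.from_arrays(mark, "WT", "chr1", starts, starts + length,
                                   np.full(len(starts), value))


def brute_force_bins(gene, params):
    """Per-base oriented bin index over the full window (oracle)."""
    intervals = oriented_bin_intervals(gene, params)
    lo = int(intervals[:, 0].min())
    hi = int(intervals[:, 1].max())
    lookup = {}
    for idx, (s, e) in enumerate(intervals):
        for pos in range(int(s), int(e)):
            assert pos not in lookup, "bins overlap"
        for pos in range(int(s), int(e)):
            lookup[pos] = idx
    return lo, hi, lookup


class TestBinGeometry:
    def test_body_bins_tile_gene_exactly(self):
        rng = np.random.default_rng(2)
        params = AnalysisParams()
        for _ in range(1000):
            length = int(rng.integers(params.n_body_bins, 5000))
            gene = make_gene("+" if rng.integers(2) else "-", 10000, length)
            iv = oriented_bin_intervals(gene, params)
            body = iv[params.n_flank_bins:params.n_flank_bins + params.n_body_bins]
            covered = sorted((int(s), int(e)) for s, e in body)
            assert covered[0][0] == gene.tx_start
            assert covered[-1][1] == gene.tx_end
            assert all(a[1] == b[0] for a, b in zip(covered, covered[1:]))

    def test_remainder_bases_go_to_five_prime_bins(self):
        gene = make_gene("+", 0, 203)  # 20 bins: 3 bins of 11, 17 of 10
        iv = oriented_bin_intervals(gene, AnalysisParams())
        body = iv[10:30]
        sizes = [int(e - s) for s, e in body]
        assert sizes == [11, 11, 11] + [10] * 17
        minus = make_gene("-", 0, 203)
        body_m = oriented_bin_intervals(minus, AnalysisParams())[10:30]
        sizes_m = (body_m[:, 1] - body_m[:, 0]).tolist()
        assert sizes_m == [11, 11, 11] + [10] * 17  # 5'-first on minus strand too
        assert body_m[0].tolist() == [203 - 11, 203]  # 5'-most bin is rightmost

    def test_too_short_gene_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            oriented_bin_intervals(make_gene(length=10), AnalysisParams())


class TestBinAssignment:
    def test_plus_strand_body_bin(self):
        gene = make_gene("+", 0, 2000)
        # 100-bp body bins; midpoint 150 -> body bin 1 -> overall index 11
        assert assign_bin_indices(gene, np.array([150]))[0] == 10 + 1

    def test_minus_strand_reverses(self):
        gene = make_gene("-", 0, 2000)
        assert assign_bin_indices(gene, np.array([150]))[0] == 10 + 18

    def test_upstream_flank_bin(self):
        gene = make_gene("+", 10000, 5000)
        # window [5000,10000), 500-bp bins; position 7000 -> upstream bin 4
        assert assign_bin_indices(gene, np.array([7000]))[0] == 4

    def test_matches_brute_force_lookup(self):
        rng = np.random.default_rng(4)
        params = AnalysisParams()
        for _ in range(25):
            gene = make_gene(
                "+" if rng.integers(2) else "-",
                int(rng.integers(6000, 40000)),
                int(rng.integers(100, 20000)),
            )
            lo, hi, lookup = brute_force_bins(gene, params)
            mids = rng.integers(lo - 500, hi + 500, 400)
            got = assign_bin_indices(gene, mids, params)
            want = np.array([lookup.get(int(m), -1) for m in mids])
            np.testing.assert_array_equal(got, want)


class TestBinProfile:
    def test_empty_track_gives_all_missing_profile(self):
        gene = make_gene("+", 10000, 2000)
        track = SignalTrack.from_arrays("MIRA", "WT", "chr1",
                                        np.array([0]), np.array([50]), np.array([1.0]))
        prof = bin_gene_profile(gene, track)
        assert np.isnan(prof.values).all()
        assert (prof.n_probes == 0).all()

    def test_strand_reversal_reverses_vector_exactly(self):
        rng = np.random.default_rng(6)
        starts = np.arange(0, 30000, 100)
        track = SignalTrack.from_arrays(
            "MIRA", "WT", "chr1", starts, starts + 50, rng.normal(size=len(starts))
        )
        for _ in range(30):
            length = 20 * int(rng.integers(5, 500))  # palindromic bin sizes
            gene_p = make_gene("+", int(rng.integers(6000, 9000)), length)
            gene_m = make_gene("-", gene_p.tx_start, length)
            vp = bin_gene_profile(gene_p, track).values
            vm = bin_gene_profile(gene_m, track).values
            np.testing.assert_array_equal(vp, vm[::-1])


class TestComposite:
    def prof(self, values, gene_id="g", mark="MIRA"):
        arr = np.asarray(values, float)
        n = np.where(np.isnan(arr), 0, 1).astype(int)
        return BinProfile(gene_id, mark, "WT", arr, n)

    def test_mean_and_missing_handling(self):
        comp = composite_profile(
            [self.prof([1.0, np.nan]), self.prof([3.0, 5.0])], "grp"
        )
        assert comp.mean.tolist() == [2.0, 5.0]
        assert comp.n_genes.tolist() == [2, 1]

    def test_single_gene_identity(self):
        comp = composite_profile([self.prof([1.5, -0.5])])
        assert comp.mean.tolist() == [1.5, -0.5]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composite_profile([])

    def test_partition_merge_consistency(self):
        rng = np.random.default_rng(7)
        profs = [self.prof(np.where(rng.random(8) < 0.2, np.nan, rng.normal(size=8)),
                           gene_id=f"g{i}") for i in range(20)]
        whole = composite_profile(profs)
        part_a, part_b = composite_profile(profs[:7]), composite_profile(profs[7:])
        na, nb = part_a.n_genes, part_b.n_genes
        with np.errstate(invalid="ignore"):
            merged = (np.nan_to_num(part_a.mean) * na + np.nan_to_num(part_b.mean) * nb
                      ) / (na + nb)
        defined = whole.n_genes > 0
        np.testing.assert_allclose(merged[defined], whole.mean[defined])


class TestClustering:
    def matrix(self, rows, ids=None):
        arr = np.asarray(rows, float)
        ids = ids or [f"g{i}" for i in range(len(arr))]
        return pd.DataFrame(arr, index=pd.Index(ids, name="gene_id"))

    def test_identical_rows_adjacent(self):
        m = self.matrix([[0, 0, 0], [9, 9, 9], [0, 0, 0]], ["a", "b", "c"])
        result = cluster_profile_matrix(m)
        order = list(result.leaf_order)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(12)
        m = self.matrix(rng.normal(size=(12, 6)))
        base = cluster_profile_matrix(m).leaf_order
        shuffled = m.sample(frac=1.0, random_state=1)
        assert cluster_profile_matrix(shuffled).leaf_order == base

    def test_all_missing_row_dropped_with_warning(self):
        m = self.matrix([[1, 2], [np.nan, np.nan], [3, 4]])
        with pytest.warns(UserWarning, match="all-missing"):
            result = cluster_profile_matrix(m)
        assert "g1" not in result.leaf_order

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(13)
        centers = np.array([[4.0, 0, 0], [0, 4.0, 0], [0, 0, 4.0]])
        rows, truth = [], []
        for k in range(3):
            rows.append(centers[k] + 0.05 * rng.normal(size=(30, 3)))
            truth.extend([k] * 30)
        m = self.matrix(np.vstack(rows))
        result = cluster_profile_matrix(m)
        labels = hierarchy.fcluster(result.linkage, t=3, criterion="maxclust")
        truth_sorted = [truth[int(g[1:])] for g in m.sort_index().index]
        assert adjusted_rand_score(truth_sorted, labels) == 1.0
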