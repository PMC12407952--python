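"""Jaccard/ANI transform, pairwise matrices, linkage clustering, centroids."""

import itertools
import math

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from sbtax.bloom import filter_from_signature
from sbtax.kmers import KmerSignature, extract_kmers
from sbtax.similarity import (PairwiseMatrix, ani_from_jaccard, average_linkage,
                              centroid, jaccard, pairwise_ani)


def sig(values, k=15):
    return KmerSignature(k, np.array(sorted(set(values)), dtype=np.uint64))


class TestJaccard:
    def test_identical(self):
        a = sig([1, 2, 3])
        assert jaccard(a, a) == 1.0

    def test_disjoint(self):
        assert jaccard(sig([1, 2]), sig([3, 4])) == 0.0

    def test_half_overlap(self):
        # |A∩B| = 2, |A∪B| = 4
        assert jaccard(sig([1, 2, 3]), sig([2, 3, 4])) == 0.5

    def test_empty_pair_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert jaccard(sig([]), sig([])) == 1.0

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            jaccard(sig([1], k=15), sig([1], k=9))

    def test_sketch_mode_converges_to_exact(self):
        # ≥10³ k-mers in filters kept below density 0.3
        rng = np.random.default_rng(13)
        a = sig(rng.integers(0, 2**40, 3000))
        b_vals = np.concatenate([a.kmers[:2000],
                                 rng.integers(2**41, 2**42, 1500).astype(np.uint64)])
        b = sig(b_vals)
        exact = jaccard(a, b)
        m = 60_000
        fa = filter_from_signature(a, m)
        fb = filter_from_signature(b, m)
        assert fa.density() <= 0.3 and fb.density() <= 0.3
        assert abs(jaccard(fa, fb) - exact) <= 0.05


class TestAniTransform:
    def test_identity_maps_to_100(self):
        for k in (5, 9, 15, 31):
            assert ani_from_jaccard(1.0, k) == 100.0

    def test_zero_clamps_to_floor(self):
        assert ani_from_jaccard(0.0, 9) == 0.0
        assert ani_from_jaccard(0.0, 9, clamp=False) == -math.inf

    def test_matches_independent_evaluation(self):
        # direct numeric evaluation of the Mash transform
        j, k = 0.5, 9
        expected = (1.0 + (1.0 / k) * math.log(2 * j / (1 + j))) * 100.0
        assert ani_from_jaccard(j, k) == pytest.approx(expected, abs=1e-9)
        assert ani_from_jaccard(j, k) == pytest.approx(95.4948321, abs=1e-6)
        # cross-check against the Mash distance formulation 100·(1−d)
        d = -(1.0 / k) * math.log(2 * j / (1 + j))
        assert ani_from_jaccard(j, k) == pytest.approx(100 * (1 - d), abs=1e-9)

    def test_monotone_in_j_and_k(self):
        js = np.linspace(0.01, 1.0, 50)
        anis = [ani_from_jaccard(j, 9, clamp=False) for j in js]
        assert all(a < b for a, b in zip(anis, anis[1:]))
        ks = range(2, 30)
        by_k = [ani_from_jaccard(0.4, k, clamp=False) for k in ks]
        assert all(a < b for a, b in zip(by_k, by_k[1:]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ani_from_jaccard(1.2, 9)
        with pytest.raises(ValueError):
            ani_from_jaccard(0.5, 0)


class TestPairwiseMatrix:
    def test_identical_genomes_100(self):
        a = sig(range(100))
        m = pairwise_ani(["x", "y"], [a, a])
        assert m.values[0, 1] == 100.0

    def test_symmetric_and_unit_diagonal(self):
        rng = np.random.default_rng(3)
        sigs = [sig(rng.integers(0, 10_000, 500)) for _ in range(5)]
        m = pairwise_ani(list("abcde"), sigs)
        assert np.array_equal(m.values, m.values.T)
        assert (np.diag(m.values) == 100.0).all()

    def test_entries_match_scalar_recomputation(self):
        rng = np.random.default_rng(4)
        sigs = [sig(rng.integers(0, 5_000, 800)) for _ in range(5)]
        m = pairwise_ani(list("abcde"), sigs)
        for i in range(5):
            for j in range(i + 1, 5):
                expected = ani_from_jaccard(jaccard(sigs[i], sigs[j]), 15)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_tsv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        sigs = [sig(rng.integers(0, 5_000, 300)) for _ in range(3)]
        m = pairwise_ani(["g1", "g2", "g3"], sigs)
        m.to_tsv(tmp_path / "ani.tsv")
        back = PairwiseMatrix.from_tsv(tmp_path / "ani.tsv")
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values)


def matrix_from_ani(ids, pairs):
    n = len(ids)
    values = np.full((n, n), 100.0)
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        values[i, j] = values[j, i] = v
    return PairwiseMatrix(list(ids), values)


def brute_force_partition(matrix, cut):
    """Unique partition with all within-pairs ≥ cut and cross-pairs < cut."""
    ids = matrix.ids
    best = None
    for assignment in itertools.product(range(len(ids)), repeat=len(ids)):
        blocks = {}
        for gid, b in zip(ids, assignment):
            blocks.setdefault(b, []).append(gid)
        valid = True
        for block in blocks.values():
            for a, b in itertools.combinations(block, 2):
                if matrix.ani_of(a, b) < cut:
                    valid = False
        for b1, b2 in itertools.combinations(blocks.values(), 2):
            for a in b1:
                for b in b2:
                    if matrix.ani_of(a, b) >= cut:
                        valid = False
        if valid:
            partition = frozenset(frozenset(b) for b in blocks.values())
            if best is not None and partition != best:
                return None  # ambiguous instance
            best = partition
    return best


class TestAverageLinkage:
    def test_three_genome_example(self):
        m = matrix_from_ani("ABC", {("A", "B"): 99, ("A", "C"): 60, ("B", "C"): 60})
        blocks = {frozenset(b) for b in average_linkage(m, 95).blocks()}
        assert blocks == {frozenset("AB"), frozenset("C")}

    def test_low_cut_single_cluster(self):
        m = matrix_from_ani("ABC", {("A", "B"): 50, ("A", "C"): 20, ("B", "C"): 30})
        assert len(average_linkage(m, 0.001).blocks()) == 1

    def test_cut_100_all_distinct_gives_singletons(self):
        m = matrix_from_ani("ABC", {("A", "B"): 99, ("A", "C"): 98, ("B", "C"): 97})
        assert len(average_linkage(m, 100).blocks()) == 3

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(50, 99, size=(6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 100.0)
        m = PairwiseMatrix(list("abcdef"), values)
        trace = average_linkage(m, 95).linkage_trace
        heights = [h for _, _, h in trace]
        assert heights == sorted(heights)

    def test_matches_scipy_average_linkage(self):
        # independent oracle on a tie-free random matrix
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 7
            values = rng.uniform(40, 99.5, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 100.0)
            ids = [f"g{i}" for i in range(n)]
            m = PairwiseMatrix(ids, values)
            cut = rng.uniform(50, 99)
            ours = average_linkage(m, cut)
            Z = sch.linkage(squareform(100.0 - values, checks=False), method="average")
            flat = sch.fcluster(Z, t=100.0 - cut, criterion="distance")
            scipy_blocks = {}
            for gid, c in zip(ids, flat):
                scipy_blocks.setdefault(c, set()).add(gid)
            assert {frozenset(b) for b in ours.blocks()} == \
                {frozenset(b) for b in scipy_blocks.values()}

    def test_matches_brute_force_on_separated_instances(self):
        rng = np.random.default_rng(30)
        cut = 95.0
        for _ in range(20):
            n = rng.integers(3, 8)
            n_blocks = rng.integers(1, n + 1)
            truth = rng.integers(0, n_blocks, size=n)
            ids = [f"g{i}" for i in range(n)]
            values = np.full((n, n), 100.0)
            for i in range(n):
                for j in range(i + 1, n):
                    if truth[i] == truth[j]:
                        v = rng.uniform(97.5, 99.9)   # within: ≥ cut + gap
                    else:
                        v = rng.uniform(60.0, 90.0)   # between: ≤ cut − 2·gap
                    values[i, j] = values[j, i] = v
            m = PairwiseMatrix(ids, values)
            expected = brute_force_partition(m, cut)
            assert expected is not None
            got = frozenset(frozenset(b) for b in average_linkage(m, cut).blocks())
            assert got == expected


class TestCentroid:
    def test_maximizes_summed_ani(self):
        m = matrix_from_ani("ABC", {("A", "B"): 98, ("B", "C"): 98, ("A", "C"): 96})
        assert centroid(["A", "B", "C"], m) == "B"

    def test_singleton(self):
        m = matrix_from_ani("AB", {("A", "B"): 90})
        assert centroid(["A"], m) == "A"

    def test_tie_breaks_lexicographically(self):
        m = matrix_from_ani("ABC", {("A", "B"): 95, ("B", "C"): 95, ("A", "C"): 95})
        assert centroid(["B", "A", "C"], m) == "A"

    def test_order_invariant(self):
        m = matrix_from_ani("ABCD", {("A", "B"): 98, ("B", "C"): 97, ("A", "C"): 96,
                                     ("A", "D"): 90, ("B", "D"): 91, ("C", "D"): 92})
        members = ["A", "B", "C", "D"]
        results = {centroid(list(p), m) for p in itertools.permutations(members)}
        assert len(results) == 1

    def test_missing_member_raises(self):
        m = matrix_from_ani("AB", {("A", "B"): 90})
        with pytest.raises(KeyError):
            centroid(["A", "Z"], m)
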