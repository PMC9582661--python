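import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from semirigid import (
    SegmentLabeling,
    UsageError,
    agglomerate,
    circular_edges,
    cut_groups,
    cut_point_value,
    dissimilarity_matrix,
)
from semirigid.consensus import Dendrogram

from conftest import block_matrix, random_symmetric_matrix


def random_segment_labeling(rng, n_segments, n_atoms, k):
    return SegmentLabeling(rng.integers(1, k + 1, size=(n_segments, n_atoms)), k)


class TestDissimilarity:
    def test_always_cocluster_zero(self):
        seg = SegmentLabeling(np.ones((10, 4), dtype=int), 2)
        assert np.all(dissimilarity_matrix(seg).delta == 0.0)

    def test_paper_worked_example(self, rng):
        # atoms differ in 30 of 500 segments -> delta = 0.06
        labels = np.ones((500, 2), dtype=int)
        differ = rng.choice(500, size=30, replace=False)
        labels[differ, 1] = 2
        cons = dissimilarity_matrix(SegmentLabeling(labels, 2))
        assert cons.delta[0, 1] == pytest.approx(0.06, abs=0)

    def test_constant_labels_binary_delta(self, rng):
        row = rng.integers(1, 4, size=6)
        seg = SegmentLabeling(np.tile(row, (20, 1)), 3)
        delta = dissimilarity_matrix(seg).delta
        assert set(np.unique(delta)) <= {0.0, 1.0}

    def test_counts_are_integral(self, rng):
        seg = random_segment_labeling(rng, 37, 8, 3)
        cons = dissimilarity_matrix(seg)
        counts = cons.delta * seg.n_segments
        assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_similarity_duality(self, rng):
        cons = dissimilarity_matrix(random_segment_labeling(rng, 10, 5, 2))
        assert np.allclose(cons.similarity + cons.delta, 1.0)

    def test_label_identity_irrelevant(self, rng):
        # relabeling clusters within a segment must not change delta
        seg = random_segment_labeling(rng, 15, 6, 3)
        permuted = seg.labels.copy()
        for s in range(15):
            perm = rng.permutation(3) + 1
            permuted[s] = perm[seg.labels[s] - 1]
        a = dissimilarity_matrix(seg).delta
        b = dissimilarity_matrix(SegmentLabeling(permuted, 3)).delta
        assert np.array_equal(a, b)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        seg = random_segment_labeling(rng, int(rng.integers(1, 20)), 10, int(rng.integers(2, 5)))
        d = dissimilarity_matrix(seg).delta
        # d_ij <= d_il + d_lj for every triple (i, j, l)
        assert np.all(d[:, :, None] <= d[:, None, :] + d[None, :, :] + 1e-12)


class TestAgglomerate:
    def test_two_perfect_blocks(self):
        delta = block_matrix([3, 2])
        for method in ("average", "complete"):
            den = agglomerate(delta, method)
            assert den.heights[-1] == pytest.approx(1.0)
            part = cut_groups(den, 2)
            assert np.array_equal(part.group_of, [1, 1, 1, 2, 2])

    @pytest.mark.parametrize("method", ["average", "complete"])
    def test_matches_scipy_reference(self, rng, method):
        for _ in range(10):
            n = int(rng.integers(4, 12))
            delta = random_symmetric_matrix(rng, n)
            den = agglomerate(delta, method)
            ref = scipy_linkage(squareform(delta, checks=False), method=method)
            assert np.allclose(np.sort(den.heights), np.sort(ref[:, 2]), atol=1e-12)

    def test_equal_offdiagonal_merges_at_constant_height(self):
        c = 0.3
        delta = np.full((5, 5), c)
        np.fill_diagonal(delta, 0.0)
        den = agglomerate(delta, "average")
        assert np.allclose(den.heights, c)

    def test_heights_monotone(self, rng):
        for method in ("average", "complete"):
            delta = random_symmetric_matrix(rng, 15)
            h = agglomerate(delta, method).heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_single_atom_rejected(self):
        with pytest.raises(UsageError):
            agglomerate(np.zeros((1, 1)))

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(UsageError):
            agglomerate(random_symmetric_matrix(rng, 4), "ward")


class TestCut:
    def test_extreme_cuts(self, rng):
        delta = random_symmetric_matrix(rng, 6)
        den = agglomerate(delta)
        assert cut_groups(den, 6).sizes.tolist() == [1] * 6
        assert cut_groups(den, 1).sizes.tolist() == [6]

    def test_groups_numbered_by_descending_size(self):
        delta = block_matrix([2, 4])
        part = cut_groups(agglomerate(delta), 2)
        assert part.sizes.tolist() == [4, 2]
        assert np.array_equal(part.group_of, [2, 2, 1, 1, 1, 1])

    def test_cut_point_midpoint(self):
        den = Dendrogram(n_leaves=3, merges=[(0, 1, 0.2, 2), (2, 3, 0.4, 3)])
        assert cut_point_value(den, 2) == pytest.approx(0.3)

    def test_cut_point_equal_heights(self):
        den = Dendrogram(n_leaves=3, merges=[(0, 1, 0.5, 2), (2, 3, 0.5, 3)])
        assert cut_point_value(den, 2) == pytest.approx(0.5)

    def test_cut_point_between_straddling_heights(self, rng):
        delta = random_symmetric_matrix(rng, 10)
        den = agglomerate(delta)
        h = den.heights
        for ng in range(2, 10):
            cp = cut_point_value(den, ng)
            lo, hi = h[10 - 1 - ng], h[10 - ng]
            assert lo - 1e-12 <= cp <= hi + 1e-12

    def test_cut_point_out_of_range(self, rng):
        den = agglomerate(random_symmetric_matrix(rng, 5))
        for bad in (1, 5):
            with pytest.raises(UsageError):
                cut_point_value(den, bad)

    def test_partition_consistent_with_dendrogram_sizes(self, rng):
        delta = random_symmetric_matrix(rng, 12)
        for ng in (2, 4, 7):
            part = cut_groups(agglomerate(delta), ng)
            assert part.sizes.sum() == 12
            assert part.n_groups == ng
            assert sorted(part.sizes, reverse=True) == part.sizes.tolist()


class TestCircularEdges:
    def test_thresholds(self, rng):
        delta = random_symmetric_matrix(rng, 6)
        all_pairs = circular_edges(delta, 1.0)
        assert len(all_pairs) == 15
        perfect = circular_edges(delta, 0.0)
        assert perfect == [(i, j) for i, j in all_pairs if delta[i, j] == 0]

    def test_monotone_in_threshold(self, rng):
        seg = random_segment_labeling(rng, 25, 10, 3)
        delta = dissimilarity_matrix(seg).delta
        small = set(circular_edges(delta, 0.04))
        large = set(circular_edges(delta, 0.1))
        assert small <= large

    def test_residue_naming(self, rng):
        delta = np.zeros((3, 3))
        edges = circular_edges(delta, 0.5, residue_numbers=[101, 102, 103])
        assert (101, 102) in edges and (102, 103) in edges


class TestPipelineEquivariance:
    def test_permuting_atoms_permutes_outputs(self, rng):
        seg = random_segment_labeling(rng, 30, 8, 3)
        perm = rng.permutation(8)
        seg_p = SegmentLabeling(seg.labels[:, perm], 3)
        d = dissimilarity_matrix(seg).delta
        d_p = dissimilarity_matrix(seg_p).delta
        assert np.array_equal(d_p, d[np.ix_(perm, perm)])
        part = cut_groups(agglomerate(d), 3)
        part_p = cut_groups(agglomerate(d_p), 3)
        # group labels may renumber; partition structure must map through perm
        from semirigid import adjusted_rand_index

        assert adjusted_rand_index(part.group_of[perm], part_p.group_of) == pytest.approx(1.0)
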