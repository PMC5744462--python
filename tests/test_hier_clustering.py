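import numpy as np
import pytest

from swmclust.fiber_metrics import pairwise_d_me, sparse_pairwise
from swmclust.hier_clustering import (
    AffinityGraph,
    Dendrogram,
    adaptive_partition,
    average_link_dendrogram,
    build_affinity_graph,
    reproducibility_cutoff,
    reproducibility_filter,
    Partition,
)
from swmclust.tract_io import resample_fiber

from conftest import random_fiber, straight_fiber


def dense_upgma_oracle(affinity: np.ndarray):
    """Brute-force O(N^3) average-link agglomeration on a complete graph.

    Cluster affinity = mean affinity over all leaf pairs; merge the pair with
    maximal affinity, ties to the lowest (i, j) id pair.  Same id scheme as
    the implementation (leaves 0..N-1, internal ids continue upward).
    """
    n = affinity.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                a = np.mean([affinity[x, y] for x in clusters[i] for y in clusters[j]])
                if best is None or a > best[0] + 1e-15 or (
                    abs(a - best[0]) <= 1e-15 and (i, j) < best[1:]
                ):
                    best = (a, i, j)
        a, i, j = best
        merges.append((next_id, i, j, a))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


def complete_graph(affinity: np.ndarray) -> AffinityGraph:
    n = affinity.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return AffinityGraph(i=iu, j=ju, a=affinity[iu, ju], sigma2=60.0, n_elements=n)


class TestAffinityGraph:
    def test_zero_distance_gives_unit_affinity(self):
        from swmclust.fiber_metrics import SparseDistanceSet

        sd = SparseDistanceSet(i=[0], j=[1], d=[0.0], d_max=30.0, n_elements=3)
        g = build_affinity_graph(sd)
        assert g.a[0] == 1.0
        assert g.n_unconnected == 1

    def test_sigma_scale_evaluation(self):
        from swmclust.fiber_metrics import SparseDistanceSet

        sd = SparseDistanceSet(i=[0], j=[1], d=[60.0], d_max=60.0, n_elements=2)
        g = build_affinity_graph(sd, sigma2=60.0)
        assert g.a[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_affinity_decreasing_in_distance(self):
        from swmclust.fiber_metrics import SparseDistanceSet

        d = np.linspace(0, 30, 10)
        sd = SparseDistanceSet(
            i=np.zeros(10, int), j=np.arange(1, 11), d=d, d_max=30.0, n_elements=11
        )
        g = build_affinity_graph(sd)
        assert np.all(np.diff(g.a) < 0)

    def test_invalid_sigma_rejected(self):
        from swmclust.fiber_metrics import SparseDistanceSet

        sd = SparseDistanceSet(i=[], j=[], d=[], d_max=30.0, n_elements=0)
        with pytest.raises(ValueError):
            build_affinity_graph(sd, sigma2=0.0)


class TestAverageLink:
    def test_two_elements(self):
        g = AffinityGraph(i=[0], j=[1], a=[0.7], sigma2=60.0, n_elements=2)
        dg = average_link_dendrogram(g)
        assert dg.merges == [(2, 0, 1, 0.7)]
        assert dg.roots == [2]

    def test_three_element_hand_execution(self):
        g = AffinityGraph(
            i=[0, 1, 0], j=[1, 2, 2], a=[0.9, 0.5, 0.4], sigma2=60.0, n_elements=3
        )
        dg = average_link_dendrogram(g)
        assert dg.merges[0] == (3, 0, 1, 0.9)
        node, left, right, aff = dg.merges[1]
        assert {left, right} == {2, 3}
        assert aff == pytest.approx(0.45, abs=1e-12)

    def test_unconnected_elements_stay_roots(self):
        g = AffinityGraph(i=[0], j=[1], a=[0.8], sigma2=60.0, n_elements=4)
        dg = average_link_dendrogram(g)
        assert len(dg.merges) == 1  # N - nC = 4 - 2
        assert set(dg.roots) == {2, 3, 4}

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_oracle_on_complete_graphs(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 30))
        d = rng.uniform(0, 50, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        affinity = np.exp(-d / 60.0)
        dg = average_link_dendrogram(complete_graph(affinity))
        oracle = dense_upgma_oracle(affinity)
        assert len(dg.merges) == len(oracle) == n - 1
        for got, exp in zip(dg.merges, oracle):
            assert got[0] == exp[0]
            assert {got[1], got[2]} == {exp[1], exp[2]}
            assert got[3] == pytest.approx(exp[3], abs=1e-9)

    def test_merge_affinities_non_increasing(self, rng):
        n = 40
        d = rng.uniform(0, 50, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dg = average_link_dendrogram(complete_graph(np.exp(-d / 60.0)))
        affs = [m[3] for m in dg.merges]
        assert all(a >= b - 1e-9 for a, b in zip(affs, affs[1:]))

    def test_merge_count_equals_n_minus_components(self, rng):
        # each connected component (isolated elements included) ends as one
        # root, so the merge count is N minus the component count
        fibers = [resample_fiber(random_fiber(rng, scale=15.0), 21) for _ in range(60)]
        sd = sparse_pairwise(fibers, d_max=20.0)
        g = build_affinity_graph(sd)
        dg = average_link_dendrogram(g)
        assert len(dg.merges) == g.n_elements - g.n_components
        assert len(dg.roots) == g.n_components

    def test_text_round_trip(self, tmp_path):
        g = AffinityGraph(
            i=[0, 1, 0], j=[1, 2, 2], a=[0.9, 0.5, 0.4], sigma2=60.0, n_elements=3
        )
        dg = average_link_dendrogram(g)
        dg.to_text(tmp_path / "dendro.txt")
        back = Dendrogram.from_text(tmp_path / "dendro.txt")
        assert back.n_leaves == dg.n_leaves
        assert back.roots == dg.roots
        assert [(m[0], m[1], m[2]) for m in back.merges] == [
            (m[0], m[1], m[2]) for m in dg.merges
        ]


def _blob(center, n, rng, spread=2.0):
    base = straight_fiber(np.asarray(center), np.asarray(center) + [0, 0, 45.0])
    return [base + rng.normal(0, spread / 3, size=3) for _ in range(n)]


class TestAdaptivePartition:
    def test_tight_set_is_one_cluster(self, rng):
        fibers = _blob([0, 0, 0], 12, rng)
        sd = sparse_pairwise(fibers, d_max=30.0)
        dg = average_link_dendrogram(build_affinity_graph(sd))
        part = adaptive_partition(dg, fibers, d_clmax=30.0)
        assert len(part) == 1
        assert len(part.clusters[0]) == 12

    def test_all_far_gives_singletons(self, rng):
        fibers = [
            straight_fiber([100.0 * k, 0, 0], [100.0 * k, 0, 45]) for k in range(5)
        ]
        sd = sparse_pairwise(fibers, d_max=30.0)
        dg = average_link_dendrogram(build_affinity_graph(sd))
        part = adaptive_partition(dg, fibers, d_clmax=30.0)
        assert len(part) == 5
        assert all(len(c) == 1 for c in part.clusters)

    def test_two_blobs_recovered(self, rng):
        fibers = _blob([0, 0, 0], 8, rng) + _blob([60, 0, 0], 8, rng)
        sd = sparse_pairwise(fibers, d_max=70.0)
        dg = average_link_dendrogram(build_affinity_graph(sd))
        part = adaptive_partition(dg, fibers, d_clmax=30.0)
        groups = {frozenset(map(int, c)) for c in part.clusters}
        assert groups == {frozenset(range(8)), frozenset(range(8, 16))}

    @pytest.mark.parametrize("trial", range(5))
    def test_soundness_and_maximality(self, trial):
        rng = np.random.default_rng(3000 + trial)
        fibers = [resample_fiber(random_fiber(rng, scale=20.0), 21) for _ in range(50)]
        d_clmax = 25.0
        sd = sparse_pairwise(fibers, d_max=d_clmax)
        dg = average_link_dendrogram(build_affinity_graph(sd))
        part = adaptive_partition(dg, fibers, d_clmax=d_clmax)
        # partition covers all leaves exactly once
        all_leaves = np.sort(np.concatenate(part.clusters))
        assert np.array_equal(all_leaves, np.arange(50))
        stacked = np.asarray(fibers)
        leaf_sets = dg.leaf_sets()
        parents = {}
        for node, left, right, _ in dg.merges:
            parents[left] = node
            parents[right] = node
        for cluster in part.clusters:
            # soundness: recomputed max pairwise distance within bound
            dmat = pairwise_d_me(stacked[cluster], stacked[cluster])
            assert dmat.max() <= d_clmax + 1e-9
            # maximality: the parent's descendant set violates the bound
            node = next(
                nid
                for nid, leaves in leaf_sets.items()
                if len(leaves) == len(cluster) and set(leaves) == set(cluster)
            )
            if node in parents:
                pl = leaf_sets[parents[node]]
                pmat = pairwise_d_me(stacked[pl], stacked[pl])
                assert pmat.max() > d_clmax

    def test_matches_oracle_tree_partition(self):
        # when all pairwise distances are <= d_max the graph is complete and
        # cutting the oracle's tree with the same rule must agree
        rng = np.random.default_rng(77)
        fibers = [resample_fiber(random_fiber(rng, scale=10.0), 21) for _ in range(20)]
        dmat = pairwise_d_me(fibers, fibers)
        d_max = float(dmat.max()) + 1.0
        sd = sparse_pairwise(fibers, d_max=d_max)
        dg = average_link_dendrogram(build_affinity_graph(sd))
        oracle_merges = dense_upgma_oracle(np.exp(-dmat / 60.0))
        d_clmax = float(np.median(dmat))
        part = adaptive_partition(dg, fibers, d_clmax=d_clmax)
        # partition the oracle tree by the same breadth-first rule
        leaves = {i: [i] for i in range(20)}
        children = {}
        for node, left, right, _ in oracle_merges:
            leaves[node] = leaves[left] + leaves[right]
            children[node] = (left, right)
        queue = [oracle_merges[-1][0]]
        expected = set()
        while queue:
            node = queue.pop(0)
            ls = leaves[node]
            if dmat[np.ix_(ls, ls)].max() <= d_clmax:
                expected.add(frozenset(ls))
            else:
                queue.extend(children[node])
        got = {frozenset(map(int, c)) for c in part.clusters}
        assert got == expected


class TestReproducibilityFilter:
    def test_printed_cutoff_anchor(self):
        assert reproducibility_cutoff(37, 0.75) == 28

    def test_ceiling_rule(self):
        assert reproducibility_cutoff(27, 0.75) == 21  # ceil(20.25)
        assert reproducibility_cutoff(36, 0.75) == 27  # exact multiple stays

    def test_keep_and_drop_around_cutoff(self):
        clusters = [np.arange(28), np.arange(27)]
        part = Partition(clusters=clusters, d_clmax=30.0)
        subject_of = {i: f"s{i}" for i in range(28)}  # distinct subjects
        kept = reproducibility_filter(part, subject_of, n_subjects=37, min_frac=0.75)
        assert len(kept.clusters) == 1
        assert len(kept.clusters[0]) == 28

    def test_single_subject_cluster_dropped(self):
        part = Partition(clusters=[np.arange(10)], d_clmax=30.0)
        subject_of = {i: "only" for i in range(10)}
        kept = reproducibility_filter(part, subject_of, n_subjects=4, min_frac=0.75)
        assert len(kept.clusters) == 0

    def test_unmapped_leaf_raises(self):
        part = Partition(clusters=[np.array([0, 1])], d_clmax=30.0)
        with pytest.raises(KeyError):
            reproducibility_filter(part, {0: "a"}, n_subjects=2)
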