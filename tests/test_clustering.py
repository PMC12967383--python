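"""Average-linkage agglomeration: linkage oracle, cuts, Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from shapeclust.clustering import (
    ClusterAssignment,
    DistanceMatrix,
    agglomerate,
    assignments_to_records,
    average_linkage,
    cut,
    to_newick,
)
from shapeclust.errors import (
    ClusterCountError,
    DegenerateMatrixError,
    OverlapError,
    UnknownLabelError,
)
from shapeclust.measures import TimeSeries, pairwise_distance_matrix


def random_dm(rng, n, labels=None):
    v = rng.uniform(0.1, 10.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(labels=labels or [f"L{i}" for i in range(n)], values=v)


def oracle_linkage(q, r, dm):
    """Independent brute-force mean of cross-pair entries."""
    pairs = [dm.entry(x, y) for x in q for y in r]
    return sum(pairs) / len(pairs)


def oracle_min_pair(clusters, dm):
    """Brute-force global-minimum cluster pair under average linkage.

    clusters: list of label tuples in current id order; returns (height,
    index pair) with the implementation's documented tie-break.
    """
    label_pos = {lab: i for i, lab in enumerate(dm.labels)}
    best = None
    for (i, q), (j, r) in itertools.combinations(enumerate(clusters), 2):
        h = oracle_linkage(q, r, dm)
        fa = min(min(label_pos[x] for x in q), min(label_pos[y] for y in r))
        fb = max(min(label_pos[x] for x in q), min(label_pos[y] for y in r))
        key = (h, fa, fb)
        if best is None or key < best[0]:
            best = (key, (i, j))
    return best[0][0], best[1]


class TestDistanceMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))


class TestAverageLinkage:
    @pytest.fixture
    def dm3(self):
        v = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
        return DistanceMatrix(["A", "B", "C"], v)

    def test_singletons_reduce_to_entry(self, dm3):
        assert average_linkage({"A"}, {"B"}, dm3) == 2.0

    def test_cross_pair_mean(self, dm3):
        assert average_linkage({"A"}, {"B", "C"}, dm3) == pytest.approx(3.0)

    def test_symmetry(self, dm3):
        assert average_linkage({"A", "B"}, {"C"}, dm3) == average_linkage(
            {"C"}, {"A", "B"}, dm3)

    def test_overlap_rejected(self, dm3):
        with pytest.raises(OverlapError):
            average_linkage({"A", "B"}, {"B", "C"}, dm3)

    def test_unknown_label_rejected(self, dm3):
        with pytest.raises(UnknownLabelError):
            average_linkage({"A"}, {"Z"}, dm3)


class TestAgglomerate:
    def test_two_leaves_single_merge(self):
        dm = DistanceMatrix(["x", "y"], np.array([[0.0, 3.5], [3.5, 0.0]]))
        tree = agglomerate(dm)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == 3.5

    def test_too_small_rejected(self):
        with pytest.raises(DegenerateMatrixError):
            agglomerate(DistanceMatrix(["only"], np.zeros((1, 1))))

    def test_shift_pairs_merge_first_at_zero(self, rng):
        """Vertical shifts of the same curve are at proximity zero, so the
        two shift pairs are the first two (height-0) merges."""
        years = np.arange(1963, 1963 + 30)
        a = rng.uniform(0, 50, 30)
        b = np.cumsum(rng.uniform(0, 5, 30))  # a different, non-shift shape
        panel = [
            TimeSeries("A", years, a),
            TimeSeries("A+1", years, a + 1),
            TimeSeries("B", years, b),
            TimeSeries("B+2", years, b + 2),
        ]
        tree = agglomerate(pairwise_distance_matrix(panel))
        h = tree.heights()
        assert h[0] == pytest.approx(0.0, abs=1e-10)
        assert h[1] == pytest.approx(0.0, abs=1e-10)
        first_two = {frozenset(tree.members(m.new_id)) for m in tree.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_every_merge_is_bruteforce_minimal(self, rng):
        """Each merge attains the global minimum average linkage (oracle
        recomputed independently), on random 8-leaf matrices."""
        for _ in range(25):
            dm = random_dm(rng, 8)
            tree = agglomerate(dm)
            clusters = {i: (lab,) for i, lab in enumerate(dm.labels)}
            next_id = 8
            for m in tree.merges:
                current = [clusters[i] for i in sorted(clusters)]
                min_h, _ = oracle_min_pair(current, dm)
                assert m.height == pytest.approx(min_h, rel=1e-12)
                assert average_linkage(
                    set(clusters[m.a]), set(clusters[m.b]), dm
                ) == pytest.approx(m.height, rel=1e-12)
                clusters[next_id] = clusters.pop(m.a) + clusters.pop(m.b)
                next_id += 1

    def test_heights_nondecreasing(self, rng):
        for _ in range(100):
            tree = agglomerate(random_dm(rng, 8))
            h = tree.heights()
            assert all(h[i] <= h[i + 1] + 1e-12 for i in range(len(h) - 1))

    def test_heights_match_scipy_average_linkage(self, rng):
        """Independent cross-check: merge heights equal scipy's average-
        linkage heights (distinct random distances, so no tie ambiguity)."""
        for _ in range(20):
            dm = random_dm(rng, 9)
            ours = agglomerate(dm).heights()
            theirs = scipy_linkage(squareform(dm.values), method="average")[:, 2]
            np.testing.assert_allclose(ours, theirs, rtol=1e-10)

    def test_label_permutation_invariance(self, rng):
        dm = random_dm(rng, 7)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)])
        for k in (2, 3, 4):
            a1 = cut(agglomerate(dm), k).groups()
            a2 = cut(agglomerate(dm2), k).groups()
            assert {frozenset(g) for g in a1.values()} == {
                frozenset(g) for g in a2.values()}


class TestCut:
    @pytest.fixture
    def tree(self, rng):
        return agglomerate(random_dm(rng, 8))

    def test_k_equals_n_all_singletons(self, tree):
        a = cut(tree, 8)
        assert sorted(a.mapping.values()) == list(range(1, 9))

    def test_k_one_single_cluster(self, tree):
        a = cut(tree, 1)
        assert set(a.mapping.values()) == {1}
        assert set(a.mapping) == set(tree.leaf_labels)

    @pytest.mark.parametrize("k", [0, 9, -1])
    def test_out_of_range_rejected(self, tree, k):
        with pytest.raises(ClusterCountError):
            cut(tree, k)

    def test_cuts_are_nested(self, rng):
        """Every cluster at k+1 lies inside exactly one cluster at k."""
        for _ in range(20):
            tree = agglomerate(random_dm(rng, 8))
            parts = {k: cut(tree, k) for k in (2, 3, 4)}
            for k in (3, 4):
                fine = parts[k].groups().values()
                coarse = parts[k - 1].groups().values()
                for grp in fine:
                    assert sum(set(grp) <= set(c) for c in coarse) == 1

    def test_cluster_indices_follow_first_leaf_order(self, tree):
        a = cut(tree, 3)
        firsts = {}
        for leaf in tree.leaf_labels:  # input order
            c = a.mapping[leaf]
            firsts.setdefault(c, leaf)
        assert list(firsts) == sorted(firsts)

    def test_assignment_records_flatten(self, tree):
        recs = assignments_to_records([cut(tree, 2), cut(tree, 3)])
        assert len(recs) == 16
        assert {r["k"] for r in recs} == {2, 3}


class TestNewick:
    def test_two_leaf_branch_lengths_half_height(self):
        dm = DistanceMatrix(["x", "y"], np.array([[0.0, 4.0], [4.0, 0.0]]))
        nwk = to_newick(agglomerate(dm))
        assert nwk == "(x:2,y:2);"

    def test_special_characters_quoted_and_roundtrip(self, rng):
        labels = ["lung & tracheal", "colon, rectum (C18)", "plain"]
        dm = random_dm(rng, 3, labels=labels)
        nwk = to_newick(agglomerate(dm))
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == set(labels)

    def test_roundtrip_preserves_topology(self, rng):
        dm = random_dm(rng, 6)
        tree = agglomerate(dm)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        assert {lf.taxon.label for lf in parsed.leaf_node_iter()} == set(dm.labels)
        # bipartitions of the parsed tree must match the merge-tree clusters
        parsed_clades = set()
        for node in parsed.preorder_internal_node_iter():
            parsed_clades.add(frozenset(
                lf.taxon.label for lf in node.leaf_iter()))
        our_clades = set()
        for m in tree.merges:
            our_clades.add(frozenset(
                tree.leaf_labels[i] for i in tree.members(m.new_id)))
        assert our_clades <= parsed_clades

    def test_leaf_depths_are_ultrametric(self, rng):
        """Root-to-leaf path length equals half the final merge height."""
        dm = random_dm(rng, 5)
        tree = agglomerate(dm)
        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        depths = [lf.distance_from_root() for lf in parsed.leaf_node_iter()]
        np.testing.assert_allclose(depths, tree.heights()[-1] / 2, rtol=1e-9)


def test_cluster_assignment_groups_partition():
    a = ClusterAssignment(k=2, mapping={"a": 1, "b": 2, "c": 1})
    assert a.groups() == {1: ["a", "c"], 2: ["b"]}
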