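"""Mapping/score/rank matrices, correlation distances, WPGMA, subtree selection."""

import numpy as np
import pytest

from interdct.clustering import (
    LinkageTree,
    MappingMatrix,
    ScoreMatrix,
    TreeNode,
    correlation_distance_matrix,
    rank_rows,
    score_matrix,
    select_query_subtree,
    wpgma_cluster,
)
from interdct.conservation import ConservationProfile
from interdct.structure import ResidueKey


def keys(*numbers):
    return frozenset(ResidueKey("A", n, "", "ALA") for n in numbers)


def flat_profile(pid, numbers, value=1.0):
    return ConservationProfile(
        protein_id=pid, scores={ResidueKey("A", n, "", "ALA"): value for n in numbers}
    )


def make_matrix(cells, ids, query_id):
    return MappingMatrix(ids=tuple(ids), query_id=query_id, cells=tuple(tuple(r) for r in cells))


class TestScoreMatrix:
    def test_cell_smaller_than_k_uses_all_residues(self):
        m = make_matrix(
            [[keys(1, 2, 3), frozenset()], [frozenset(), frozenset()]],
            ["T", "Q"], "Q",
        )
        profiles = {"T": flat_profile("T", range(1, 10), 0.5), "Q": flat_profile("Q", [], 0.5)}
        sm = score_matrix(m, profiles, k=8)
        assert sm.values[0, 0] == pytest.approx(1.5)

    def test_uniform_profile_full_cell_scores_k(self):
        m = make_matrix(
            [[keys(*range(1, 9)), frozenset()], [frozenset(), frozenset()]],
            ["T", "Q"], "Q",
        )
        profiles = {"T": flat_profile("T", range(1, 9)), "Q": flat_profile("Q", [])}
        sm = score_matrix(m, profiles, k=8)
        assert sm.values[0, 0] == pytest.approx(8.0)

    def test_top_k_restricts_to_most_frequent_with_conservation_tiebreak(self):
        # row of T: residues 1..8 appear twice (both sources), 9..12 once;
        # k=8 keeps 1..8 only, so the second cell scores only its 1..8 part
        cell_a = keys(*range(1, 9))
        cell_b = keys(*range(1, 13))
        m = make_matrix(
            [[cell_a, cell_b, frozenset()],
             [frozenset()] * 3,
             [frozenset()] * 3],
            ["T", "S", "Q"], "Q",
        )
        profiles = {pid: flat_profile(pid, range(1, 13)) for pid in ("T", "S", "Q")}
        sm = score_matrix(m, profiles, k=8)
        assert sm.values[0, 0] == pytest.approx(8.0)
        assert sm.values[0, 1] == pytest.approx(8.0)  # only the 8 frequent ones count

    def test_random_mode_is_deterministic_in_seed(self):
        m = make_matrix(
            [[keys(*range(1, 13)), frozenset()], [frozenset(), frozenset()]],
            ["T", "Q"], "Q",
        )
        profiles = {
            "T": ConservationProfile(
                protein_id="T",
                scores={ResidueKey("A", n, "", "ALA"): n / 12 for n in range(1, 13)},
            ),
            "Q": flat_profile("Q", []),
        }
        a = score_matrix(m, profiles, k=8, mode="random", seed=5)
        b = score_matrix(m, profiles, k=8, mode="random", seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        c = score_matrix(m, profiles, k=8, mode="random", seed=6)
        assert not np.array_equal(a.values, c.values)


class TestRankRows:
    def _rank(self, row):
        sm = ScoreMatrix(ids=("a", "b", "c"), query_id="c", values=np.array([row]))
        return rank_rows(sm).ranks[0].tolist()

    def test_strictly_decreasing_row(self):
        assert self._rank([3.2, 1.1, 0.0]) == [1, 2, 3]

    def test_tied_values_get_average_rank(self):
        assert self._rank([2.0, 2.0, 0.0]) == [1.5, 1.5, 3]

    def test_all_zero_row_is_total_tie(self):
        assert self._rank([0.0, 0.0, 0.0]) == [2.0, 2.0, 2.0]


class TestCorrelationDistance:
    def test_identical_rows_have_zero_distance(self):
        rows = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        d = correlation_distance_matrix(rows)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_rank_rows_have_distance_two(self):
        rows = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        assert correlation_distance_matrix(rows)[0, 1] == pytest.approx(2.0)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(9)
        rows = rng.permuted(np.tile(np.arange(1.0, 7.0), (4, 1)), axis=1)
        d = correlation_distance_matrix(rows)
        for i in range(4):
            for j in range(4):
                u, v = rows[i] - rows[i].mean(), rows[j] - rows[j].mean()
                r = (u @ v) / np.sqrt((u @ u) * (v @ v))
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_row_gets_unit_distance(self):
        rows = np.array([[2.0, 2, 2, 2], [1.0, 2, 3, 4], [4.0, 2, 3, 1]])
        d = correlation_distance_matrix(rows)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[0, 2] == pytest.approx(1.0)
        assert d[0, 0] == 0.0


def brute_force_wpgma(d):
    """Independent reference agglomerator (list-of-members representation)."""
    n = len(d)
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i][j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], min(clusters[kv[0][0]]), min(clusters[kv[0][1]])))
        merges.append((sorted(clusters[a] + clusters[b]), h))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        for other in [c for c in clusters if c != next_id]:
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            dist[(other, next_id)] = (da + db) / 2
        dist.pop((min(a, b), max(a, b)), None)
        next_id += 1
    return merges


class TestWpgma:
    def test_three_leaf_hand_agglomeration(self):
        d = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
        tree = wpgma_cluster(d, ["A", "B", "C"])
        assert sorted(tree.merge_heights()) == pytest.approx([0.1, 0.4])
        assert sorted(tree.root.children[0].leaves() if not tree.root.children[0].is_leaf
                      else tree.root.children[1].leaves()) == ["A", "B"]

    def test_two_leaves_merge_at_their_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = wpgma_cluster(d, ["A", "B"])
        assert tree.root.height == pytest.approx(0.7)

    def test_matches_brute_force_reference_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(5, 8))
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = wpgma_cluster(d, [f"L{i}" for i in range(n)])
            ref = brute_force_wpgma(d.tolist())
            assert sorted(tree.merge_heights()) == pytest.approx(
                sorted(h for _, h in ref), abs=1e-12
            )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            wpgma_cluster(d, ["A", "B"])

    def test_matches_scipy_weighted_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 8))
            m = rng.random((n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = wpgma_cluster(d, [f"L{i}" for i in range(n)])
            z = linkage(squareform(d, checks=False), method="weighted")
            assert sorted(tree.merge_heights()) == pytest.approx(
                sorted(z[:, 2].tolist()), abs=1e-12
            )


def chain_tree(heights, query="Q", n_templates=3):
    """Caterpillar tree: query nested deepest, one template per level."""
    node = TreeNode(height=heights[-1], children=(
        TreeNode(height=0, leaf_name=query), TreeNode(height=0, leaf_name="T0")))
    for i, h in enumerate(reversed(heights[:-1]), start=1):
        node = TreeNode(height=h, children=(node, TreeNode(height=0, leaf_name=f"T{i}")))
    names = tuple([query] + [f"T{i}" for i in range(len(heights))])
    return LinkageTree(root=node, leaf_names=names)


class TestSelectQuerySubtree:
    def test_largest_gap_selects_lower_node(self):
        tree = chain_tree([1.0, 0.9, 0.2, 0.1])
        subset = select_query_subtree(tree, "Q")
        # gap 0.9 -> 0.2 dominates; leaves under the 0.2 node: Q, T0, T1
        assert set(subset.template_ids) == {"T0", "T1"}
        assert subset.gap == pytest.approx(0.7)

    def test_two_leaf_tree_returns_other_leaf(self):
        tree = LinkageTree(
            root=TreeNode(height=0.5, children=(
                TreeNode(height=0, leaf_name="Q"), TreeNode(height=0, leaf_name="T"))),
            leaf_names=("Q", "T"),
        )
        assert select_query_subtree(tree, "Q").template_ids == ("T",)

    def test_equal_gaps_resolve_toward_query(self):
        tree = chain_tree([1.0, 0.75, 0.5])  # gaps exactly 0.25 and 0.25
        subset = select_query_subtree(tree, "Q")
        assert set(subset.template_ids) == {"T0"}  # query-proximal pair wins

    def test_single_leaf_tree_rejected(self):
        tree = LinkageTree(root=TreeNode(height=0, leaf_name="Q"), leaf_names=("Q",))
        with pytest.raises(ValueError):
            select_query_subtree(tree, "Q")
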