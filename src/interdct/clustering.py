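"""Template selection by clustering conservation-weighted mapping profiles.

The pipeline implemented here: every template's interface is mapped onto
every other protein (templates plus query), giving a square matrix of residue
sets; each row's sets are scored by summing the conservation of the top-k
(default 8) most frequently mapped residues of that row; rows are converted
to ranks; pairwise Pearson correlation of rank rows defines a distance
matrix; WPGMA agglomeration yields a dendrogram; and the query's template
subset is the subtree below the largest height gap on the root-to-query path.

The query contributes an empty source column throughout (its interface is
unknown), so under ranking it receives the worst rank in every row — the
structural signature that clustering is driven only by the templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .conservation import ConservationProfile
from .contacts import InterfaceDefinition
from .mapping import ResidueEquivalenceMap, burial_filter, map_interface
from .structure import ResidueKey, SasaMap

logger = logging.getLogger(__name__)

__all__ = [
    "MappingMatrix",
    "ScoreMatrix",
    "RankMatrix",
    "TreeNode",
    "LinkageTree",
    "TemplateSubset",
    "build_mapping_matrix",
    "score_matrix",
    "rank_rows",
    "correlation_distance_matrix",
    "wpgma_cluster",
    "select_query_subtree",
]


@dataclass(frozen=True)
class MappingMatrix:
    """Square matrix of mapped-and-filtered interface residue sets.

    Rows index the *target* protein (the profile being scored), columns the
    *source* template whose interface was mapped.  The query's source column
    is empty by construction; each template's diagonal cell is its own
    interface.
    """

    ids: tuple[str, ...]
    query_id: str
    cells: tuple[tuple[frozenset[ResidueKey], ...], ...]

    @property
    def n(self) -> int:
        return len(self.ids)

    def cell(self, target: str, source: str) -> frozenset[ResidueKey]:
        return self.cells[self.ids.index(target)][self.ids.index(source)]


@dataclass(frozen=True)
class ScoreMatrix:
    ids: tuple[str, ...]
    query_id: str
    values: np.ndarray  # (n, n) float


@dataclass(frozen=True)
class RankMatrix:
    ids: tuple[str, ...]
    query_id: str
    ranks: np.ndarray  # (n, n) float; 1 = highest score, average ranks on ties


@dataclass
class TreeNode:
    """A node of the merge tree; leaves carry a name, internal nodes a height."""

    height: float
    children: tuple["TreeNode", "TreeNode"] | None = None
    leaf_name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_name]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass(frozen=True)
class LinkageTree:
    root: TreeNode
    leaf_names: tuple[str, ...]

    def path_to_leaf(self, name: str) -> list[TreeNode]:
        """Internal nodes from the root down to (excluding) the leaf ``name``."""
        path: list[TreeNode] = []
        node = self.root
        while not node.is_leaf:
            path.append(node)
            left, right = node.children  # type: ignore[misc]
            node = left if name in left.leaves() else right
            if name not in node.leaves():
                raise KeyError(f"leaf {name!r} not in tree")
        if node.leaf_name != name:
            raise KeyError(f"leaf {name!r} not in tree")
        return path

    def merge_heights(self) -> list[float]:
        heights: list[float] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return sorted(heights)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.leaf_name}:{length:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        return fmt(self.root, self.root.height) + ";"


@dataclass(frozen=True)
class TemplateSubset:
    """The selected template ids and the height gap that selected them."""

    template_ids: tuple[str, ...]
    gap: float


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------

def build_mapping_matrix(
    ids: Sequence[str],
    query_id: str,
    interfaces: Mapping[str, InterfaceDefinition],
    equivalences: Mapping[tuple[str, str], ResidueEquivalenceMap],
    sasa: Mapping[str, SasaMap],
    min_sasa: float = 5.0,
) -> MappingMatrix:
    """Map every template's interface onto every protein and burial-filter.

    ``interfaces`` covers every template (not the query); ``equivalences`` is
    keyed by ordered ``(source, target)`` pairs and must cover every pair with
    a template source.
    """
    ids = tuple(ids)
    if query_id not in ids:
        raise ValueError("query id must be included in ids")
    rows = []
    for target in ids:
        row = []
        for source in ids:
            if source == query_id:
                row.append(frozenset())
            elif source == target:
                row.append(interfaces[source].residues)
            else:
                eq = equivalences.get((source, target))
                if eq is None:
                    raise KeyError(f"missing equivalence for pair ({source}, {target})")
                mapped = map_interface(interfaces[source], eq)
                row.append(burial_filter(mapped.residues, sasa[target], min_sasa))
        rows.append(tuple(row))
    return MappingMatrix(ids=ids, query_id=query_id, cells=tuple(rows))


def _residue_sort_key(key: ResidueKey) -> tuple:
    return (key.chain_id, key.seq_number, key.insertion_code, key.residue_name)


def score_matrix(
    matrix: MappingMatrix,
    profiles: Mapping[str, ConservationProfile],
    k: int = 8,
    mode: str = "frequency",
    seed: int | None = None,
) -> ScoreMatrix:
    """Conservation-sum scores restricted to each row's top-k residues.

    ``mode="frequency"`` (default): for each target row, residues are ranked
    by how often they are mapped across that row's source cells (ties broken
    by higher conservation in the target's profile, then residue order); a
    cell's score sums the target-profile conservation of its residues that
    fall in the row's top-k.  ``mode="random"`` replaces the top-k selection
    by sampling k residues uniformly without replacement within each cell
    (seeded) — the alternative-clustering mode used for confidence
    measurement.  Cells with fewer than k eligible residues use all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("frequency", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    n = matrix.n
    values = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for ti, target in enumerate(matrix.ids):
        profile = profiles[target]
        row = matrix.cells[ti]
        if mode == "frequency":
            freq: dict[ResidueKey, int] = {}
            for cell in row:
                for r in cell:
                    freq[r] = freq.get(r, 0) + 1
            ordered = sorted(
                freq,
                key=lambda r: (-freq[r], -profile.score(r), _residue_sort_key(r)),
            )
            top = set(ordered[:k])
            for si in range(n):
                values[ti, si] = sum(profile.score(r) for r in row[si] if r in top)
        else:
            for si in range(n):
                cell = sorted(row[si], key=_residue_sort_key)
                if len(cell) > k:
                    chosen = rng.choice(len(cell), size=k, replace=False)
                    cell = [cell[i] for i in chosen]
                values[ti, si] = sum(profile.score(r) for r in cell)
    return ScoreMatrix(ids=matrix.ids, query_id=matrix.query_id, values=values)


def rank_rows(sm: ScoreMatrix) -> RankMatrix:
    """Per-row dense ranks, 1 = highest score, ties by average rank."""
    from scipy.stats import rankdata

    ranks = np.vstack([rankdata(-row, method="average") for row in sm.values])
    return RankMatrix(ids=sm.ids, query_id=sm.query_id, ranks=ranks)


def correlation_distance_matrix(rm: RankMatrix | np.ndarray) -> np.ndarray:
    """d(u, v) = 1 − Pearson(u, v) between rank rows.

    Rows with zero variance get unit distance to every other row (logged).
    """
    rows = rm.ranks if isinstance(rm, RankMatrix) else np.asarray(rm, float)
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 rows")
    std = rows.std(axis=1)
    constant = std == 0
    if constant.any():
        logger.warning("%d constant rank rows; using unit distance", int(constant.sum()))
    d = np.ones((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        sub = rows[ok]
        c = np.corrcoef(sub)
        d[np.ix_(ok, ok)] = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ---------------------------------------------------------------------------
# WPGMA clustering
# ---------------------------------------------------------------------------

def wpgma_cluster(distance: np.ndarray, leaf_names: Sequence[str]) -> LinkageTree:
    """Weighted-average (WPGMA) agglomerative clustering.

    At each step the closest pair of clusters merges at their current
    distance; the merged cluster's distance to any other is the unweighted
    mean of its two parents' distances.  Ties are broken deterministically by
    the lowest leaf index contained in each candidate cluster.
    """
    distance = np.asarray(distance, dtype=float)
    n = len(leaf_names)
    if distance.shape != (n, n):
        raise ValueError("distance matrix shape does not match leaf count")
    if not np.allclose(distance, distance.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    # active clusters: id -> (min original leaf index, TreeNode)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, leaf_name=leaf_names[i]) for i in range(n)
    }
    min_leaf = {i: i for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(distance[i, j])
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(min_leaf[kv[0][0]], min_leaf[kv[0][1]]),
                max(min_leaf[kv[0][0]], min_leaf[kv[0][1]]),
            ),
        )
        (a, b), d = best
        node = TreeNode(height=d, children=(nodes[a], nodes[b]))
        nodes[next_id] = node
        min_leaf[next_id] = min(min_leaf[a], min_leaf[b])
        active.discard(a)
        active.discard(b)
        for other in active:
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            dist[(min(other, next_id), max(other, next_id))] = (da + db) / 2.0
        dist.pop((a, b), None)
        active.add(next_id)
        next_id += 1
    root_id = active.pop()
    return LinkageTree(root=nodes[root_id], leaf_names=tuple(leaf_names))


def select_query_subtree(tree: LinkageTree, query_leaf: str) -> TemplateSubset:
    """Pick the template subset below the largest height gap above the query.

    The internal nodes whose subtree contains the query are listed from the
    root down; the pair of contiguous nodes with the largest height
    difference is found (ties resolved toward the query), and the leaves
    under the lower node — minus the query itself — form the subset.
    """
    if len(tree.leaf_names) < 2:
        raise ValueError("tree with a single leaf has no template subset")
    path = tree.path_to_leaf(query_leaf)
    if len(path) == 1:
        lower = path[0]
        gap = lower.height
    else:
        heights = [node.height for node in path]
        diffs = [heights[i] - heights[i + 1] for i in range(len(heights) - 1)]
        best = max(range(len(diffs)), key=lambda i: (diffs[i], i))
        lower = path[best + 1]
        gap = diffs[best]
    templates = tuple(name for name in lower.leaves() if name != query_leaf)
    if not templates:
        # degenerate: lower node contains only the query; fall back one level
        templates = tuple(name for name in path[-1].leaves() if name != query_leaf)
    return TemplateSubset(template_ids=templates, gap=float(gap))
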